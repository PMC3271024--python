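import numpy as np
import pytest

from sacstrat import (
    ObserverPolicy,
    PsychometricParams,
    build_decision_schedule,
    exp2_size_truth_family,
    optimal_switch_separation,
)

S01_SCHEDULE = [8.0, 8.85, 9.85, 10.85, 11.85, 12.85, 13.85, 14.85, 24.0]


@pytest.fixture(scope="session")
def s01_psi():
    """Sensitivity function resembling the printed S01 fit: near-perfect at
    the fovea, chance in the far periphery, 75%-point at 5.93 degrees."""
    return PsychometricParams(alpha=1.0, beta=0.5, e_half=5.93, gamma=1.0)


@pytest.fixture(scope="session")
def s01_schedule():
    return list(S01_SCHEDULE)


@pytest.fixture(scope="session")
def s01_prediction(s01_psi, s01_schedule):
    return optimal_switch_separation(s01_psi, conditions=s01_schedule)


@pytest.fixture(scope="session")
def size_family():
    return exp2_size_truth_family()


def make_mapping_trials(params, levels, n_per_level, rng=None, exact=False):
    """Mapping trials on an eccentricity grid.

    exact=True builds deterministic counts with round(n * psi) correct
    responses per level (a noiseless-proportions oracle input); otherwise
    responses are Bernoulli draws from psi.
    """
    from sacstrat import MappingTrial, evaluate_sensitivity

    trials = []
    for e in levels:
        p = evaluate_sensitivity(params, e)
        if exact:
            k = int(round(n_per_level * p))
        else:
            k = int(rng.binomial(n_per_level, p))
        for i in range(n_per_level):
            correct = i < k
            trials.append(
                MappingTrial(
                    eccentricity=e,
                    size=1.0,
                    side="left",
                    configuration="dot-up",
                    response="dot-up" if correct else "dot-down",
                )
            )
    return trials
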