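"""Synthetic sessions with the statistical structure of the three-token task.

No raw behavioral data accompany the study design this package analyzes, so
every downstream stage is exercised on simulated sessions that reproduce the
experimental protocol: factorial sensitivity-mapping grids, observer-specific
decision schedules, fixation placement equidistant from the center and
near-side tokens, Gaussian saccade-endpoint scatter with a landing criterion,
abort-and-replay of failed trials, an independent blink/second-saccade
exclusion flag, and configurable strategy policies including a sticky
(Markov) chooser.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give identical trial tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError, UnknownConditionError
from .ideal_observer import (
    GainModel,
    StrategyPrediction,
    TaskGeometry,
    optimal_switch_separation,
    optimal_switch_size,
    strategy_probabilities,
)
from .psychometric import (
    MappingTrial,
    PsychometricParams,
    SizeSensitivityFamily,
    evaluate_sensitivity,
    evaluate_size_sensitivity,
)

__all__ = [
    "DesignSpec",
    "ObserverPolicy",
    "EndpointNoise",
    "DecisionTrial",
    "exp1_mapping_design_spec",
    "exp2_mapping_design_spec",
    "build_mapping_design",
    "simulate_mapping_responses",
    "build_decision_schedule",
    "compute_fixation_position",
    "simulate_decision_session",
    "simulate_verification_session",
]

SIDES = ("left", "right")
CONFIGURATIONS = ("dot-up", "dot-down")
DEFAULT_COMMON_SEPARATIONS = (8.0, 24.0)


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of a sensitivity-mapping session."""

    experiment: int
    eccentricity_grid: tuple[float, ...]
    size_grid: tuple[float, ...]
    repetitions: int
    sides: tuple[str, ...] = SIDES
    configurations: tuple[str, ...] = CONFIGURATIONS

    def __post_init__(self):
        if not self.eccentricity_grid or not self.size_grid:
            raise DomainError("eccentricity and size grids must be non-empty")
        if self.repetitions < 1:
            raise DomainError("repetitions must be >= 1")

    @property
    def n_trials(self) -> int:
        return (
            len(self.eccentricity_grid)
            * len(self.size_grid)
            * len(self.sides)
            * len(self.configurations)
            * self.repetitions
        )


def exp1_mapping_design_spec() -> DesignSpec:
    """Eccentricities 0-12 deg in steps of 3, token size 1 deg, 20 reps: 400 trials."""
    return DesignSpec(
        experiment=1,
        eccentricity_grid=(0.0, 3.0, 6.0, 9.0, 12.0),
        size_grid=(1.0,),
        repetitions=20,
    )


def exp2_mapping_design_spec() -> DesignSpec:
    """Sizes 0.6-1.8 deg at eccentricities {0, 6, 12} deg, 25 reps: 1500 trials."""
    return DesignSpec(
        experiment=2,
        eccentricity_grid=(0.0, 6.0, 12.0),
        size_grid=(0.6, 0.9, 1.2, 1.5, 1.8),
        repetitions=25,
    )


def exp2_size_truth_family(
    params: PsychometricParams | None = None,
    size_midpoints: Sequence[float] = (0.3, 1.0, 1.6),
    gamma: float = 0.2,
    eccentricities: Sequence[float] = (0.0, 6.0, 12.0),
) -> SizeSensitivityFamily:
    """Ground-truth size-sensitivity family for the size experiment.

    One increasing size-psi member per eccentricity in {0, 6, 12} degrees;
    larger eccentricities need larger tokens (increasing size midpoints),
    with asymptotes taken from ``params`` (default alpha=1, beta=0.5).
    """
    alpha = params.alpha if params is not None else 1.0
    beta = params.beta if params is not None else 0.5
    entries = tuple(
        (float(e), PsychometricParams(alpha=alpha, beta=beta, e_half=m, gamma=gamma))
        for e, m in zip(eccentricities, size_midpoints)
    )
    return SizeSensitivityFamily(entries=entries)


def build_mapping_design(spec: DesignSpec, seed: int = 0) -> list[MappingTrial]:
    """Full factorial crossing x repetitions, in randomized (seeded) order,
    with responses unset."""
    trials = [
        MappingTrial(
            eccentricity=e,
            size=s,
            side=side,
            configuration=cfg,
            experiment=spec.experiment,
        )
        for e in spec.eccentricity_grid
        for s in spec.size_grid
        for side in spec.sides
        for cfg in spec.configurations
        for _ in range(spec.repetitions)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def simulate_mapping_responses(
    design: Sequence[MappingTrial],
    truth: PsychometricParams | SizeSensitivityFamily,
    seed: int = 0,
) -> list[MappingTrial]:
    """Fill in responses: correct with probability psi(eccentricity) (or
    psi_E(size) when ``truth`` is a size family)."""
    rng = np.random.default_rng(seed)
    out = []
    for t in design:
        if isinstance(truth, SizeSensitivityFamily):
            p = evaluate_size_sensitivity(truth, t.eccentricity, t.size)
        else:
            p = evaluate_sensitivity(truth, t.eccentricity)
        correct = rng.random() < p
        other = "dot-down" if t.configuration == "dot-up" else "dot-up"
        out.append(replace(t, response=t.configuration if correct else other))
    return out


def build_decision_schedule(
    anchor: float,
    common_values: Sequence[float] = DEFAULT_COMMON_SEPARATIONS,
    step: float = 1.0,
    n_around: int = 7,
) -> list[float]:
    """Observer-specific condition schedule: ``n_around`` values centered on
    ``anchor`` in increments of ``step``, unioned with the common values,
    sorted and deduplicated.

    With anchor 11.85, step 1, 7 surrounding values and common {8, 24} this
    yields the nine-separation schedule [8, 8.85, ..., 14.85, 24].
    """
    if step <= 0:
        raise DomainError("step must be positive")
    if n_around < 1 or n_around % 2 == 0:
        raise DomainError("n_around must be a positive odd count")
    half = (n_around - 1) // 2
    values = [anchor + k * step for k in range(-half, half + 1)]
    values.extend(float(v) for v in common_values)
    out: list[float] = []
    for v in sorted(values):
        if not out or not math.isclose(v, out[-1], abs_tol=1e-9):
            out.append(round(v, 9))
    return out


def compute_fixation_position(
    separation: float, vertical_offset: float = 4.0, side: str = "right"
) -> tuple[float, float]:
    """Fixation cross position for side-token separation D: offset D/4 toward
    ``side`` and ``vertical_offset`` below the token row, which puts it
    exactly equidistant from the center token and the nearer side token."""
    if separation < 0:
        raise DomainError("separation must be non-negative")
    sign = 1.0 if side == "right" else -1.0
    return (sign * separation / 4.0, -float(vertical_offset))


@dataclass(frozen=True)
class ObserverPolicy:
    """How a simulated observer chooses center vs. side on each trial.

    kinds:
      ``ideal``         — the gain-maximizing step policy (deterministic);
      ``fixed-mixture`` — side with probability ``p_side_base``, i.i.d.;
      ``sticky-markov`` — repeat the previous trial's strategy with
                          probability ``stickiness_kappa``, otherwise redraw
                          from the base rate;
      ``always-center`` / ``always-side`` — constant.

    ``near_side_preference`` is the chance a side saccade targets the token
    nearer to fixation; ``lapse`` replaces the chosen strategy with a
    uniform random one.
    """

    kind: Literal[
        "ideal", "fixed-mixture", "sticky-markov", "always-center", "always-side"
    ] = "ideal"
    p_side_base: float = 0.5
    stickiness_kappa: float = 0.0
    near_side_preference: float = 1.0
    lapse: float = 0.0

    def __post_init__(self):
        for name in ("p_side_base", "stickiness_kappa", "near_side_preference", "lapse"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class EndpointNoise:
    """Gaussian scatter of the saccade landing point around the intended
    token center, and the landing criterion used to abort stray trials."""

    sigma_x: float = 0.75
    sigma_y: float = 0.75
    landing_criterion_radius: float = 1.0
    blink_rate: float = 0.15

    def __post_init__(self):
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise DomainError("sigmas must be non-negative")
        if self.landing_criterion_radius <= 0:
            raise DomainError("landing criterion radius must be positive")
        if not (0.0 <= self.blink_rate < 1.0):
            raise DomainError("blink_rate must be in [0, 1)")


@dataclass(frozen=True)
class DecisionTrial:
    """One decision- or verification-phase trial."""

    index: int
    condition: float  # separation D or size S, degrees
    variable: str  # "separation" | "size"
    fixation: tuple[float, float]
    fixation_side: str
    intended_token: str  # "left" | "center" | "right"
    landing: tuple[float, float]
    latency_ms: float
    aborted: bool = False
    abort_reason: str | None = None  # "landing" | "blink"
    replayed_from: int | None = None
    target_side: str | None = None
    configuration: str | None = None
    response: str | None = None
    correct: bool | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    observer: str = "sim"


def _token_positions(separation: float) -> dict[str, tuple[float, float]]:
    return TaskGeometry(side_separation=separation).token_positions


class _StrategyChooser:
    """Draws center/side per trial according to an ObserverPolicy."""

    def __init__(
        self,
        policy: ObserverPolicy,
        prediction: StrategyPrediction | None,
        rng: np.random.Generator,
    ):
        self.policy = policy
        self.prediction = prediction
        self.rng = rng
        self.previous: str | None = None

    def choose(self, condition: float) -> str:
        p = self.policy
        if p.kind == "always-center":
            strat = "center"
        elif p.kind == "always-side":
            strat = "side"
        elif p.kind == "ideal":
            try:
                strat = self.prediction.strategy_for(condition)
            except UnknownConditionError:
                strat = self.prediction.optimal_strategy(condition)
        elif p.kind == "fixed-mixture":
            strat = "side" if self.rng.random() < p.p_side_base else "center"
        elif p.kind == "sticky-markov":
            if self.previous is not None and self.rng.random() < p.stickiness_kappa:
                strat = self.previous
            else:
                strat = "side" if self.rng.random() < p.p_side_base else "center"
        else:  # pragma: no cover - guarded by dataclass Literal
            raise ValueError(f"unknown policy kind {p.kind!r}")
        if p.lapse > 0 and self.rng.random() < p.lapse:
            strat = "side" if self.rng.random() < 0.5 else "center"
        return strat

    def commit(self, strat: str) -> None:
        """Record the strategy of a *completed* trial as the one the sticky
        chooser may repeat.  Aborted trials do not advance the chain, so the
        retained-trial sequence is itself the Markov chain the analysis sees."""
        self.previous = strat


def _simulate_session(
    schedule: Sequence[float],
    reps_per_condition: int,
    truth: PsychometricParams | SizeSensitivityFamily,
    chooser: _StrategyChooser,
    policy: ObserverPolicy,
    noise: EndpointNoise,
    gain_model: GainModel,
    rng: np.random.Generator,
    variable: str,
    side_separation: float | None,
    latency_median_ms: float,
    latency_log_sigma: float,
    observer: str,
) -> list[DecisionTrial]:
    pending = [float(c) for c in schedule for _ in range(reps_per_condition)]
    rng.shuffle(pending)
    pending = list(pending)
    replay_source = [None] * len(pending)

    trials: list[DecisionTrial] = []
    i = 0
    while i < len(pending):
        condition = pending[i]
        d = condition if variable == "separation" else float(side_separation)
        tokens = _token_positions(d)
        fix_side = SIDES[rng.integers(2)]
        fixation = compute_fixation_position(d, side=fix_side)

        strat = chooser.choose(condition)
        if strat == "center":
            intended = "center"
        else:
            near = fix_side
            far = "left" if near == "right" else "right"
            intended = near if rng.random() < policy.near_side_preference else far

        tx, ty = tokens[intended]
        landing = (
            tx + rng.normal(0.0, noise.sigma_x),
            ty + rng.normal(0.0, noise.sigma_y),
        )
        latency = float(
            rng.lognormal(math.log(latency_median_ms), latency_log_sigma)
        )

        blink = rng.random() < noise.blink_rate
        min_dist = min(
            math.hypot(landing[0] - x, landing[1] - y) for x, y in tokens.values()
        )
        if blink or min_dist > noise.landing_criterion_radius:
            reason = "blink" if blink else "landing"
            trials.append(
                DecisionTrial(
                    index=len(trials),
                    condition=condition,
                    variable=variable,
                    fixation=fixation,
                    fixation_side=fix_side,
                    intended_token=intended,
                    landing=landing,
                    latency_ms=latency,
                    aborted=True,
                    abort_reason=reason,
                    replayed_from=replay_source[i],
                    observer=observer,
                )
            )
            # Re-queue the condition at a uniformly random later position.
            pos = int(rng.integers(i + 1, len(pending) + 1))
            pending.insert(pos, condition)
            replay_source.insert(pos, len(trials) - 1)
            i += 1
            continue

        target_side = "left" if rng.random() < gain_model.p_target_left else "right"
        configuration = CONFIGURATIONS[rng.integers(2)]
        target_pos = tokens[target_side]
        if variable == "separation":
            ecc = math.hypot(landing[0] - target_pos[0], landing[1] - target_pos[1])
            p_correct = evaluate_sensitivity(truth, ecc)
        else:
            # Size sessions: the family is only defined at the nominal
            # token-center eccentricities {0, D/2, D}.
            ix, iy = tokens[intended]
            ecc = math.hypot(ix - target_pos[0], iy - target_pos[1])
            ecc = min((0.0, d / 2.0, d), key=lambda v: abs(v - ecc))
            p_correct = evaluate_size_sensitivity(truth, ecc, condition)
        correct = rng.random() < p_correct
        chooser.commit(strat)
        other = "dot-down" if configuration == "dot-up" else "dot-up"
        trials.append(
            DecisionTrial(
                index=len(trials),
                condition=condition,
                variable=variable,
                fixation=fixation,
                fixation_side=fix_side,
                intended_token=intended,
                landing=landing,
                latency_ms=latency,
                replayed_from=replay_source[i],
                target_side=target_side,
                configuration=configuration,
                response=configuration if correct else other,
                correct=correct,
                observer=observer,
            )
        )
        i += 1
    return trials


def _default_prediction(
    truth: PsychometricParams | SizeSensitivityFamily,
    variable: str,
    schedule: Sequence[float],
    side_separation: float | None,
    gain_model: GainModel,
) -> StrategyPrediction:
    if variable == "separation":
        return optimal_switch_separation(
            truth, gain_model=gain_model, conditions=schedule
        )
    geometry = TaskGeometry(side_separation=float(side_separation))
    return optimal_switch_size(truth, geometry, conditions=schedule)


def simulate_decision_session(
    schedule: Sequence[float],
    reps_per_condition: int,
    truth: PsychometricParams | SizeSensitivityFamily,
    policy: ObserverPolicy,
    noise: EndpointNoise = EndpointNoise(),
    gain_model: GainModel = GainModel(),
    seed: int = 0,
    *,
    variable: Literal["separation", "size"] = "separation",
    side_separation: float | None = None,
    prediction: StrategyPrediction | None = None,
    latency_median_ms: float = 250.0,
    latency_log_sigma: float = 0.25,
    observer: str = "sim",
) -> list[DecisionTrial]:
    """Simulate a free-choice decision session.

    Conditions (separations, or sizes at fixed ``side_separation``) are
    randomly interleaved; each trial draws a strategy from ``policy``, a side
    saccade goes to the nearer token with probability
    ``policy.near_side_preference``, the landing point is the intended token
    center plus Gaussian noise, and trials that blink or land farther than
    the criterion radius from every token are aborted and re-queued with the
    same condition.  The discrimination outcome is Bernoulli with
    psi(post-landing eccentricity of the target).
    """
    if variable == "size" and side_separation is None:
        side_separation = 12.0
    rng = np.random.default_rng(seed)
    if policy.kind == "ideal" and prediction is None:
        prediction = _default_prediction(
            truth, variable, schedule, side_separation, gain_model
        )
    chooser = _StrategyChooser(policy, prediction, rng)
    return _simulate_session(
        schedule,
        reps_per_condition,
        truth,
        chooser,
        policy,
        noise,
        gain_model,
        rng,
        variable,
        side_separation,
        latency_median_ms,
        latency_log_sigma,
        observer,
    )


def simulate_verification_session(
    schedule: Sequence[float],
    reps_per_condition: int,
    truth: PsychometricParams | SizeSensitivityFamily,
    prediction: StrategyPrediction,
    noise: EndpointNoise = EndpointNoise(),
    gain_model: GainModel = GainModel(),
    seed: int = 0,
    *,
    variable: Literal["separation", "size"] = "separation",
    side_separation: float | None = None,
    latency_median_ms: float = 250.0,
    latency_log_sigma: float = 0.25,
    observer: str = "sim",
) -> list[DecisionTrial]:
    """Simulate an instructed session: on every trial the intended token is
    the one the model-optimal strategy prescribes for that condition
    (side saccades are instructed to the nearer token)."""
    for c in schedule:
        prediction.strategy_for(float(c))  # raises if a condition is missing
    if variable == "size" and side_separation is None:
        side_separation = 12.0
    rng = np.random.default_rng(seed)
    policy = ObserverPolicy(kind="ideal", near_side_preference=1.0)
    chooser = _StrategyChooser(policy, prediction, rng)
    return _simulate_session(
        schedule,
        reps_per_condition,
        truth,
        chooser,
        policy,
        noise,
        gain_model,
        rng,
        variable,
        side_separation,
        latency_median_ms,
        latency_log_sigma,
        observer,
    )
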