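"""Configuration, trial-table I/O and end-to-end pipeline orchestration.

A single :class:`RunConfig` (YAML-serializable, seed mandatory) drives the
whole chain: simulate a sensitivity-mapping session from the configured
ground truth, fit the sensitivity function, derive the optimal switch point
and step policy, simulate decision and verification sessions, analyze them,
and write everything to an output directory as plain-text artifacts (CSV
trial tables, key-value fit/prediction/report files, a run log).  Identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior_analysis import SessionReport, analyze_session, strategy_probabilities
from .errors import ConfigError, SchemaError
from .ideal_observer import (
    GainModel,
    StrategyPrediction,
    TaskGeometry,
    optimal_switch_separation,
    optimal_switch_size,
)
from .psychometric import (
    FitResult,
    MappingTrial,
    PsychometricParams,
    fit_sensitivity,
    fit_size_family,
)
from .synthetic_data import (
    DecisionTrial,
    EndpointNoise,
    ObserverPolicy,
    build_decision_schedule,
    build_mapping_design,
    exp1_mapping_design_spec,
    exp2_mapping_design_spec,
    simulate_decision_session,
    simulate_mapping_responses,
    simulate_verification_session,
)

__all__ = [
    "RunConfig",
    "read_trials",
    "write_mapping_trials",
    "write_decision_trials",
    "run_pipeline",
]

MAPPING_COLUMNS = [
    "observer",
    "experiment",
    "eccentricity_deg",
    "size_deg",
    "side",
    "configuration",
    "response",
    "correct",
]
DECISION_COLUMNS = [
    "observer",
    "trial_index",
    "variable",
    "condition_deg",
    "fixation_x_deg",
    "fixation_y_deg",
    "fixation_side",
    "intended_token",
    "landing_x_deg",
    "landing_y_deg",
    "latency_ms",
    "aborted",
    "abort_reason",
    "replayed_from",
    "target_side",
    "configuration",
    "response",
    "correct",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one reproducible end-to-end run."""

    seed: int
    experiment: Literal[1, 2] = 1
    observer: str = "sim"
    # ground truth for simulation: eccentricity psi for experiment 1,
    # per-eccentricity size-psi members for experiment 2
    truth_alpha: float = 1.0
    truth_beta: float = 0.5
    truth_e_half: float = 5.93
    truth_gamma: float = 1.0
    reps_per_condition: int = 96
    schedule_step: float = 1.0
    schedule_n_around: int = 7
    common_separations: tuple[float, ...] = (8.0, 24.0)
    size_grid: tuple[float, ...] = (0.6, 0.9, 1.2, 1.5, 1.8)
    side_separation: float = 12.0  # experiment 2 geometry
    policy_kind: str = "sticky-markov"
    p_side_base: float = 0.5
    stickiness_kappa: float = 0.5
    near_side_preference: float = 0.85
    lapse: float = 0.0
    sigma_x: float = 0.75
    sigma_y: float = 0.75
    landing_criterion_radius: float = 1.0
    blink_rate: float = 0.15
    reward_per_correct: float = 1.0
    p_target_left: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        for name in (
            "truth_e_half",
            "truth_gamma",
            "reps_per_condition",
            "schedule_step",
            "side_separation",
            "sigma_x",
            "sigma_y",
            "landing_criterion_radius",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def truth_params(self) -> PsychometricParams:
        return PsychometricParams(
            alpha=self.truth_alpha,
            beta=self.truth_beta,
            e_half=self.truth_e_half,
            gamma=self.truth_gamma,
        )

    def policy(self) -> ObserverPolicy:
        return ObserverPolicy(
            kind=self.policy_kind,  # type: ignore[arg-type]
            p_side_base=self.p_side_base,
            stickiness_kappa=self.stickiness_kappa,
            near_side_preference=self.near_side_preference,
            lapse=self.lapse,
        )

    def noise(self) -> EndpointNoise:
        return EndpointNoise(
            sigma_x=self.sigma_x,
            sigma_y=self.sigma_y,
            landing_criterion_radius=self.landing_criterion_radius,
            blink_rate=self.blink_rate,
        )

    def gain_model(self) -> GainModel:
        return GainModel(
            reward_per_correct=self.reward_per_correct,
            p_target_left=self.p_target_left,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["common_separations"] = list(self.common_separations)
        d["size_grid"] = list(self.size_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        if "seed" not in d:
            raise ConfigError("seed is mandatory")
        for key in ("common_separations", "size_grid"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def write_mapping_trials(trials: Sequence[MappingTrial], path: str | Path) -> None:
    rows = [
        {
            "observer": t.observer,
            "experiment": t.experiment,
            "eccentricity_deg": t.eccentricity,
            "size_deg": t.size,
            "side": t.side,
            "configuration": t.configuration,
            "response": t.response if t.response is not None else "",
            "correct": "" if t.correct is None else t.correct,
        }
        for t in trials
    ]
    pd.DataFrame(rows, columns=MAPPING_COLUMNS).to_csv(path, index=False)


def write_decision_trials(trials: Sequence[DecisionTrial], path: str | Path) -> None:
    rows = [
        {
            "observer": t.observer,
            "trial_index": t.index,
            "variable": t.variable,
            "condition_deg": t.condition,
            "fixation_x_deg": t.fixation[0],
            "fixation_y_deg": t.fixation[1],
            "fixation_side": t.fixation_side,
            "intended_token": t.intended_token,
            "landing_x_deg": t.landing[0],
            "landing_y_deg": t.landing[1],
            "latency_ms": t.latency_ms,
            "aborted": t.aborted,
            "abort_reason": t.abort_reason or "",
            "replayed_from": "" if t.replayed_from is None else t.replayed_from,
            "target_side": t.target_side or "",
            "configuration": t.configuration or "",
            "response": t.response or "",
            "correct": "" if t.correct is None else t.correct,
        }
        for t in trials
    ]
    pd.DataFrame(rows, columns=DECISION_COLUMNS).to_csv(path, index=False)


def _parse_bool(value) -> bool | None:
    if value in ("", None) or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def read_trials(
    path: str | Path, schema: Literal["mapping", "decision", "verification"]
) -> list[MappingTrial] | list[DecisionTrial]:
    """Read a CSV trial table, validating the column schema and reporting
    malformed rows with their line numbers."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"trial table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = MAPPING_COLUMNS if schema == "mapping" else DECISION_COLUMNS
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for schema '{schema}'"
        )
    errors: list[str] = []
    records: list = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            if schema == "mapping":
                records.append(
                    MappingTrial(
                        eccentricity=float(row["eccentricity_deg"]),
                        size=float(row["size_deg"]),
                        side=row["side"],
                        configuration=row["configuration"],
                        response=row["response"] or None,
                        observer=row["observer"],
                        experiment=int(row["experiment"]),
                    )
                )
            else:
                records.append(
                    DecisionTrial(
                        index=int(row["trial_index"]),
                        condition=float(row["condition_deg"]),
                        variable=row["variable"],
                        fixation=(
                            float(row["fixation_x_deg"]),
                            float(row["fixation_y_deg"]),
                        ),
                        fixation_side=row["fixation_side"],
                        intended_token=row["intended_token"],
                        landing=(
                            float(row["landing_x_deg"]),
                            float(row["landing_y_deg"]),
                        ),
                        latency_ms=float(row["latency_ms"]),
                        aborted=bool(_parse_bool(row["aborted"])),
                        abort_reason=row["abort_reason"] or None,
                        replayed_from=(
                            int(row["replayed_from"]) if row["replayed_from"] else None
                        ),
                        target_side=row["target_side"] or None,
                        configuration=row["configuration"] or None,
                        response=row["response"] or None,
                        correct=_parse_bool(row["correct"]),
                        observer=row["observer"],
                    )
                )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(
            f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors[:20])
        )
    return records


def _prediction_text(
    prediction: StrategyPrediction,
    conditions: Sequence[float],
    meg: float,
    *,
    params=None,
    family=None,
    geometry=None,
    gain_model=GainModel(),
) -> str:
    lines = [
        f"variable: {prediction.variable}",
        f"switch_point_deg: {prediction.switch_point:.4f}",
        f"uniqueness_verified: {prediction.uniqueness_verified}",
        f"max_expected_gain: {meg:.4f}",
        "condition_deg,p_center,p_side,strategy",
    ]
    for c in conditions:
        pc, ps = strategy_probabilities(
            c,
            variable=prediction.variable,
            params=params,
            family=family,
            geometry=geometry,
            gain_model=gain_model,
        )
        lines.append(f"{c},{pc:.6f},{ps:.6f},{prediction.strategy_for(c)}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, out_dir: str | Path) -> SessionReport:
    """fit -> predict -> simulate -> analyze, writing all artifacts to disk.

    Child seeds are derived deterministically from the config seed; the run
    log records package versions, seeds and exclusion tallies (no
    timestamps, so reruns are byte-identical).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(int(config.seed))
    seed_map, seed_dec, seed_ver = (int(s) for s in ss.generate_state(3))

    truth = config.truth_params()
    gain_model = config.gain_model()

    if config.experiment == 1:
        design = build_mapping_design(exp1_mapping_design_spec(), seed=seed_map)
        mapping = simulate_mapping_responses(design, truth, seed=seed_map)
        fit = fit_sensitivity(mapping, seed=int(config.seed))
        anchor_pred = optimal_switch_separation(fit.params)
        schedule = build_decision_schedule(
            anchor=round(anchor_pred.switch_point, 2),
            common_values=config.common_separations,
            step=config.schedule_step,
            n_around=config.schedule_n_around,
        )
        prediction = optimal_switch_separation(
            fit.params, gain_model=gain_model, conditions=schedule
        )
        model_kwargs = dict(params=fit.params, family=None, geometry=None)
        variable = "separation"
        side_sep = None
    else:
        from .synthetic_data import exp2_size_truth_family

        family_truth = exp2_size_truth_family(truth)
        design = build_mapping_design(exp2_mapping_design_spec(), seed=seed_map)
        mapping = simulate_mapping_responses(design, family_truth, seed=seed_map)
        family_fit = fit_size_family(mapping, seed=int(config.seed))
        geometry = TaskGeometry(side_separation=config.side_separation)
        schedule = list(config.size_grid)
        prediction = optimal_switch_size(family_fit, geometry, conditions=schedule)
        model_kwargs = dict(params=None, family=family_fit, geometry=geometry)
        variable = "size"
        side_sep = config.side_separation
        truth = family_truth
        fit = None

    decision = simulate_decision_session(
        schedule,
        config.reps_per_condition,
        truth,
        config.policy(),
        config.noise(),
        gain_model,
        seed=seed_dec,
        variable=variable,
        side_separation=side_sep,
        prediction=prediction,
        observer=config.observer,
    )
    verification = simulate_verification_session(
        schedule,
        config.reps_per_condition,
        truth,
        prediction,
        config.noise(),
        gain_model,
        seed=seed_ver,
        variable=variable,
        side_separation=side_sep,
        observer=config.observer,
    )

    report = analyze_session(
        decision,
        prediction,
        gain_model=gain_model,
        landing_criterion_radius=config.landing_criterion_radius,
        side_separation=side_sep,
        **model_kwargs,
    )
    ver_report = analyze_session(
        verification,
        prediction,
        gain_model=gain_model,
        landing_criterion_radius=config.landing_criterion_radius,
        side_separation=side_sep,
        **model_kwargs,
    )

    config.to_yaml(out / "config.yaml")
    write_mapping_trials(mapping, out / "mapping.csv")
    write_decision_trials(decision, out / "decision.csv")
    write_decision_trials(verification, out / "verification.csv")
    if fit is not None:
        (out / "sensitivity_fit.txt").write_text(fit.to_text())
    (out / "prediction.txt").write_text(
        _prediction_text(
            prediction, schedule, report.gain.meg, gain_model=gain_model, **model_kwargs
        )
    )
    (out / "report.txt").write_text(report.to_text())
    (out / "verification_report.txt").write_text(ver_report.to_text())
    report.proportions.to_csv(out / "proportions.csv", index=False)
    log = [
        f"python: {sys.version_info.major}.{sys.version_info.minor}",
        f"numpy: {np.__version__}",
        f"pandas: {pd.__version__}",
        f"seed: {config.seed}",
        f"seed_mapping: {seed_map}",
        f"seed_decision: {seed_dec}",
        f"seed_verification: {seed_ver}",
        "exclusions_decision: "
        + ", ".join(f"{k}={v}" for k, v in sorted(report.exclusions.items())),
        "exclusions_verification: "
        + ", ".join(f"{k}={v}" for k, v in sorted(ver_report.exclusions.items())),
    ]
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return report
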