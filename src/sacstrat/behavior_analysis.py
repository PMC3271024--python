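"""Session-level behavioral analyses for the three-token task.

Given a trial table (simulated or loaded from CSV) and an ideal-observer
prediction, this module classifies saccades by nearest token, applies the
exclusion rules (aborts, blinks/second saccades, landings beyond the
criterion radius), and computes the study's summary statistics: strategy
proportions per condition, near-side preference, inter-trial strategy
dependencies, optimality on repeated conditions, realized gain versus
maximum expected gain (MEG), a nested likelihood-ratio test of
gain-maximization, saccade endpoint statistics, latency-binned optimality,
and a re-estimate of the sensitivity function from decision-phase data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError, InsufficientDataError, UnknownConditionError
from .ideal_observer import (
    GainModel,
    StrategyPrediction,
    TaskGeometry,
    max_expected_gain,
    strategy_probabilities,
)
from .psychometric import (
    FitResult,
    MappingTrial,
    PsychometricParams,
    SizeSensitivityFamily,
    fit_sensitivity,
)
from .synthetic_data import DecisionTrial

__all__ = [
    "ClassifiedTrial",
    "SessionReport",
    "classify_saccade",
    "classify_trials",
    "apply_exclusions",
    "strategy_proportions",
    "near_side_preference",
    "intertrial_dependency",
    "estimate_stickiness",
    "repeated_condition_optimality",
    "realized_gain_and_deficit",
    "nested_lrt_vs_meg",
    "endpoint_statistics",
    "latency_vs_optimality",
    "estimate_psi_from_decision",
    "analyze_session",
]

_TOKEN_ORDER = ("center", "left", "right")  # tie-break precedence


@dataclass(frozen=True)
class ClassifiedTrial:
    """A retained decision trial plus its nearest-token assignment."""

    trial: DecisionTrial
    assigned_token: str
    strategy: str  # "center" | "side"
    optimal: bool

    @property
    def condition(self) -> float:
        return self.trial.condition


def _separation_of(trial: DecisionTrial, side_separation: float | None) -> float:
    if trial.variable == "separation":
        return trial.condition
    if side_separation is not None:
        return side_separation
    # Recover D from the fixation offset (|x| = D/4) for size sessions.
    return 4.0 * abs(trial.fixation[0])


def classify_saccade(
    landing: tuple[float, float], geometry: TaskGeometry
) -> tuple[str, str]:
    """Assign a landing point to the closest token (Euclidean distance) and
    collapse left/right to strategy 'side'.  Ties break center, then left."""
    tokens = geometry.token_positions
    best = None
    best_d = math.inf
    for name in _TOKEN_ORDER:
        x, y = tokens[name]
        d = math.hypot(landing[0] - x, landing[1] - y)
        if d < best_d - 1e-12:
            best, best_d = name, d
    strategy = "center" if best == "center" else "side"
    return best, strategy


def classify_trials(
    trials: Sequence[DecisionTrial],
    prediction: StrategyPrediction | None = None,
    side_separation: float | None = None,
) -> list[ClassifiedTrial]:
    """Classify retained (non-excluded, completed) trials in sequence order."""
    out = []
    for t in trials:
        if t.aborted or t.excluded:
            continue
        geo = TaskGeometry(side_separation=_separation_of(t, side_separation))
        token, strategy = classify_saccade(t.landing, geo)
        if prediction is not None:
            try:
                ideal = prediction.strategy_for(t.condition)
            except UnknownConditionError:
                ideal = prediction.optimal_strategy(t.condition)
            optimal = strategy == ideal
        else:
            optimal = False
        out.append(
            ClassifiedTrial(trial=t, assigned_token=token, strategy=strategy, optimal=optimal)
        )
    return out


def apply_exclusions(
    trials: Sequence[DecisionTrial],
    landing_criterion_radius: float = 1.0,
    side_separation: float | None = None,
) -> tuple[list[DecisionTrial], dict[str, int]]:
    """Drop aborted, blink/second-saccade and stray-landing trials.

    Returns the retained trials (flags filled in on the full set are
    discarded copies) and a tally of exclusion counts by reason.
    """
    tally = {"blink": 0, "landing": 0}
    retained = []
    for t in trials:
        if t.aborted:
            tally[t.abort_reason or "landing"] = tally.get(t.abort_reason or "landing", 0) + 1
            continue
        geo = TaskGeometry(side_separation=_separation_of(t, side_separation))
        min_dist = min(
            math.hypot(t.landing[0] - x, t.landing[1] - y)
            for x, y in geo.token_positions.values()
        )
        if min_dist > landing_criterion_radius:
            tally["landing"] += 1
            continue
        retained.append(t)
    return retained, tally


def strategy_proportions(
    classified: Sequence[ClassifiedTrial],
    prediction: StrategyPrediction | None = None,
    ci_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-condition proportion of side-strategy saccades with exact counts
    and binomial (Clopper-Pearson) confidence intervals, paired with the
    ideal step policy when a prediction is supplied."""
    if not classified:
        raise InsufficientDataError("no retained trials to summarize")
    rows = []
    by_cond: dict[float, list[ClassifiedTrial]] = {}
    for c in classified:
        by_cond.setdefault(float(c.condition), []).append(c)
    for cond in sorted(by_cond):
        group = by_cond[cond]
        n = len(group)
        k = sum(c.strategy == "side" for c in group)
        lo, hi = proportion_confint(k, n, alpha=ci_alpha, method="beta")
        row = {
            "condition": cond,
            "n": n,
            "n_side": k,
            "p_side": k / n,
            "ci_low": lo,
            "ci_high": hi,
        }
        if prediction is not None:
            try:
                ideal = prediction.strategy_for(cond)
            except UnknownConditionError:
                ideal = prediction.optimal_strategy(cond)
            row["ideal_p_side"] = 1.0 if ideal == "side" else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def near_side_preference(classified: Sequence[ClassifiedTrial]) -> float:
    """Among side saccades, the proportion directed to the token nearer to
    fixation (the fixation-side token)."""
    side = [c for c in classified if c.strategy == "side"]
    if not side:
        raise InsufficientDataError("no side-strategy trials; preference undefined")
    near = sum(c.assigned_token == c.trial.fixation_side for c in side)
    return near / len(side)


def _repeat_frequencies(strategies: Sequence[str]) -> dict[str, dict[str, float]]:
    out = {}
    arr = list(strategies)
    for strat in ("side", "center"):
        uncond = sum(s == strat for s in arr) / len(arr)
        pairs = [(a, b) for a, b in zip(arr[:-1], arr[1:]) if a == strat]
        cond = (
            sum(b == strat for _, b in pairs) / len(pairs) if pairs else float("nan")
        )
        out[strat] = {"conditional": cond, "unconditional": uncond}
    return out


@dataclass(frozen=True)
class DependencyResult:
    per_observer: dict[str, dict[str, dict[str, float]]]
    tests: dict[str, dict[str, float]] | None
    notice: str | None = None


def intertrial_dependency(
    classified: Sequence[ClassifiedTrial],
) -> DependencyResult:
    """Conditional vs. unconditional strategy-repeat frequencies, per
    observer, with a one-tailed paired t-test across observers that the
    conditional frequency exceeds the unconditional one."""
    by_obs: dict[str, list[str]] = {}
    for c in classified:
        by_obs.setdefault(c.trial.observer, []).append(c.strategy)
    per_obs = {}
    for obs, seq in by_obs.items():
        if len(seq) < 2:
            raise InsufficientDataError(f"observer {obs}: need >= 2 trials in sequence")
        per_obs[obs] = _repeat_frequencies(seq)
    if len(per_obs) < 2:
        return DependencyResult(
            per_observer=per_obs,
            tests=None,
            notice="fewer than 2 observers: across-observer t-test skipped",
        )
    tests = {}
    for strat in ("side", "center"):
        cond = []
        uncond = []
        for obs, freqs in per_obs.items():
            if not math.isnan(freqs[strat]["conditional"]):
                cond.append(freqs[strat]["conditional"])
                uncond.append(freqs[strat]["unconditional"])
        t, p = stats.ttest_rel(cond, uncond, alternative="greater")
        tests[strat] = {"t": float(t), "p": float(p), "df": len(cond) - 1}
    return DependencyResult(per_observer=per_obs, tests=tests)


def estimate_stickiness(
    strategies: Sequence[str], p_side_base: float = 0.5
) -> float:
    """Moment estimate of the Markov stickiness kappa under the model
    'repeat the previous strategy with probability kappa, else redraw from
    the base rate'.

    P[repeat] = kappa + (1 - kappa) * b, where b is the base probability of
    redrawing the previous strategy, so kappa = (f_repeat - b) / (1 - b).
    """
    arr = list(strategies)
    if len(arr) < 2:
        raise InsufficientDataError("need >= 2 trials to estimate stickiness")
    pairs = list(zip(arr[:-1], arr[1:]))
    f_repeat = sum(a == b for a, b in pairs) / len(pairs)
    base_same = [
        p_side_base if a == "side" else 1.0 - p_side_base for a, _ in pairs
    ]
    b = float(np.mean(base_same))
    if b >= 1.0:
        raise DomainError("degenerate base rate: repeat probability uninformative")
    return (f_repeat - b) / (1.0 - b)


@dataclass(frozen=True)
class RepeatedConditionResult:
    overall_rate: float
    repeated_rate: float
    n_repeated: int
    statistic: float | None
    p_value: float | None
    notice: str | None = None


def repeated_condition_optimality(
    classified: Sequence[ClassifiedTrial],
) -> RepeatedConditionResult:
    """Optimal-choice rate overall vs. on trials whose condition repeats the
    previous retained trial's, with a one-tailed two-proportion z-test
    (repeated > non-repeated)."""
    if len(classified) < 2:
        raise InsufficientDataError("need >= 2 trials in sequence order")
    opt = np.array([c.optimal for c in classified], dtype=float)
    conds = np.array([c.condition for c in classified], dtype=float)
    repeated = np.zeros(len(classified), dtype=bool)
    repeated[1:] = np.isclose(conds[1:], conds[:-1], atol=1e-9)
    overall = float(opt.mean())
    if not repeated.any():
        return RepeatedConditionResult(
            overall_rate=overall,
            repeated_rate=float("nan"),
            n_repeated=0,
            statistic=None,
            p_value=None,
            notice="no immediately repeated conditions in the sequence",
        )
    rep_rate = float(opt[repeated].mean())
    non = ~repeated
    p1, n1 = opt[repeated].mean(), int(repeated.sum())
    p2, n2 = opt[non].mean(), int(non.sum())
    pooled = (opt[repeated].sum() + opt[non].sum()) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        z, p = 0.0, 1.0
    else:
        z = (p1 - p2) / se
        p = float(stats.norm.sf(z))
    return RepeatedConditionResult(
        overall_rate=overall,
        repeated_rate=rep_rate,
        n_repeated=n1,
        statistic=float(z),
        p_value=p,
    )


@dataclass(frozen=True)
class GainSummary:
    realized_gain: float
    expected_gain: float
    meg: float
    deficit: float
    meg_policy: dict[float, str]


def _model_probs_for(
    condition: float,
    variable: str,
    params: PsychometricParams | None,
    family: SizeSensitivityFamily | None,
    geometry: TaskGeometry | None,
    gain_model: GainModel,
) -> tuple[float, float]:
    return strategy_probabilities(
        condition,
        variable=variable,  # type: ignore[arg-type]
        params=params,
        family=family,
        geometry=geometry,
        gain_model=gain_model,
    )


def realized_gain_and_deficit(
    classified: Sequence[ClassifiedTrial],
    prediction: StrategyPrediction,
    *,
    params: PsychometricParams | None = None,
    family: SizeSensitivityFamily | None = None,
    geometry: TaskGeometry | None = None,
    gain_model: GainModel = GainModel(),
) -> GainSummary:
    """Realized gain (reward x number correct), the model expected gain of
    the observed strategy choices, the maximum expected gain over the same
    per-condition trial counts, and the relative deficit (MEG - EG) / MEG."""
    if not classified:
        raise InsufficientDataError("no retained trials")
    variable = prediction.variable
    realized = gain_model.reward_per_correct * sum(bool(c.trial.correct) for c in classified)
    counts: dict[float, dict[str, int]] = {}
    for c in classified:
        d = counts.setdefault(float(c.condition), {"center": 0, "side": 0})
        d[c.strategy] += 1
    eg = 0.0
    cond_counts = []
    for cond, strat_counts in counts.items():
        pc, ps = _model_probs_for(cond, variable, params, family, geometry, gain_model)
        eg += gain_model.reward_per_correct * (
            strat_counts["center"] * pc + strat_counts["side"] * ps
        )
        cond_counts.append((cond, strat_counts["center"] + strat_counts["side"]))
    meg, meg_policy = max_expected_gain(
        cond_counts,
        variable=variable,
        params=params,
        family=family,
        geometry=geometry,
        gain_model=gain_model,
    )
    deficit = (meg - eg) / meg
    return GainSummary(
        realized_gain=realized,
        expected_gain=eg,
        meg=meg,
        deficit=deficit,
        meg_policy=meg_policy,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    dropped_conditions: tuple[float, ...] = ()


def nested_lrt_vs_meg(
    classified: Sequence[ClassifiedTrial],
    prediction: StrategyPrediction,
    *,
    params: PsychometricParams | None = None,
    family: SizeSensitivityFamily | None = None,
    geometry: TaskGeometry | None = None,
    gain_model: GainModel = GainModel(),
) -> LRTResult:
    """Nested-hypothesis test of gain maximization.

    Null: per-condition success counts are binomial with the success
    probability of the MEG strategy for that condition.  Alternative: one
    free success probability per condition (its MLE is the observed
    proportion).  The statistic 2*(logL_alt - logL_null) is referred to a
    chi-square with one degree of freedom per retained condition.
    """
    if not classified:
        raise InsufficientDataError("no retained trials")
    variable = prediction.variable
    counts: dict[float, list[int]] = {}
    for c in classified:
        n_k = counts.setdefault(float(c.condition), [0, 0])
        n_k[0] += 1
        n_k[1] += int(bool(c.trial.correct))
    stat = 0.0
    df = 0
    dropped = []
    for cond in sorted(counts):
        n, k = counts[cond]
        if n == 0:
            dropped.append(cond)
            continue
        pc, ps = _model_probs_for(cond, variable, params, family, geometry, gain_model)
        p0 = max(pc, ps)
        p0 = min(max(p0, 1e-12), 1 - 1e-12)
        phat = k / n
        ll_null = k * math.log(p0) + (n - k) * math.log(1 - p0)
        ll_alt = 0.0
        if 0 < k:
            ll_alt += k * math.log(phat)
        if k < n:
            ll_alt += (n - k) * math.log(1 - phat)
        stat += 2.0 * (ll_alt - ll_null)
        df += 1
    stat = max(stat, 0.0)
    p_value = float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p_value=p_value, dropped_conditions=tuple(dropped))


def endpoint_statistics(
    classified: Sequence[ClassifiedTrial],
    side_separation: float | None = None,
) -> pd.DataFrame:
    """Per-token mean landing offset from the token center and the
    horizontal/vertical standard deviations of the landing scatter."""
    rows = []
    by_token: dict[str, list[tuple[float, float]]] = {}
    for c in classified:
        geo = TaskGeometry(side_separation=_separation_of(c.trial, side_separation))
        tx, ty = geo.token_positions[c.assigned_token]
        by_token.setdefault(c.assigned_token, []).append(
            (c.trial.landing[0] - tx, c.trial.landing[1] - ty)
        )
    for token in _TOKEN_ORDER:
        if token not in by_token:
            continue
        offs = np.array(by_token[token])
        flagged = len(offs) < 2
        rows.append(
            {
                "token": token,
                "n": len(offs),
                "mean_dx": float(offs[:, 0].mean()),
                "mean_dy": float(offs[:, 1].mean()),
                "sd_x": float(offs[:, 0].std(ddof=1)) if not flagged else float("nan"),
                "sd_y": float(offs[:, 1].std(ddof=1)) if not flagged else float("nan"),
                "insufficient": flagged,
            }
        )
    return pd.DataFrame(rows)


def latency_vs_optimality(
    classified: Sequence[ClassifiedTrial], n_bins: int = 4
) -> pd.DataFrame:
    """Quantile-bin latencies and report the per-bin proportion of trials on
    which the chosen strategy was the model-optimal one."""
    if n_bins > len(classified):
        raise InsufficientDataError(
            f"n_bins={n_bins} exceeds the {len(classified)} available trials"
        )
    lat = np.array([c.trial.latency_ms for c in classified])
    opt = np.array([c.optimal for c in classified], dtype=float)
    if np.ptp(lat) == 0:
        return pd.DataFrame(
            [
                {
                    "bin": 0,
                    "latency_low": float(lat[0]),
                    "latency_high": float(lat[0]),
                    "n": len(lat),
                    "p_optimal": float(opt.mean()),
                    "notice": "constant latency: single bin",
                }
            ]
        )
    edges = np.quantile(lat, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, lat, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b,
                "latency_low": float(edges[b]),
                "latency_high": float(edges[b + 1]),
                "n": int(mask.sum()),
                "p_optimal": float(opt[mask].mean()),
                "notice": "",
            }
        )
    return pd.DataFrame(rows)


def estimate_psi_from_decision(
    classified: Sequence[ClassifiedTrial],
    side_separation: float | None = None,
    method: Literal["least-squares", "max-likelihood"] = "least-squares",
    seed: int = 0,
) -> FitResult:
    """Refit psi(E) from decision/verification trials: each retained trial
    contributes (eccentricity from the landed token center to the target,
    correct).  Requires >= 3 distinct post-landing eccentricities."""
    pseudo = []
    for c in classified:
        t = c.trial
        geo = TaskGeometry(side_separation=_separation_of(t, side_separation))
        ax, ay = geo.token_positions[c.assigned_token]
        tx, ty = geo.token_positions[t.target_side]
        ecc = round(math.hypot(ax - tx, ay - ty), 9)
        pseudo.append(
            MappingTrial(
                eccentricity=ecc,
                size=geo.token_size,
                side=t.target_side,
                configuration=t.configuration,
                response=t.response,
            )
        )
    distinct = {p.eccentricity for p in pseudo}
    if len(distinct) < 3:
        raise InsufficientDataError(
            f"only {len(distinct)} distinct post-landing eccentricities; need >= 3"
        )
    return fit_sensitivity(pseudo, method=method, seed=seed)


@dataclass(frozen=True)
class SessionReport:
    """Bundle of the session-level statistics, serializable to text + CSV."""

    proportions: pd.DataFrame
    switch_point: float
    variable: str
    gain: GainSummary
    near_side: float | None
    dependency: DependencyResult
    repeated: RepeatedConditionResult
    lrt: LRTResult
    exclusions: dict[str, int]
    n_retained: int

    def to_text(self) -> str:
        lines = [
            f"variable: {self.variable}",
            f"switch_point_deg: {self.switch_point:.4f}",
            f"n_retained: {self.n_retained}",
            f"exclusions: " + ", ".join(f"{k}={v}" for k, v in sorted(self.exclusions.items())),
            f"realized_gain: {self.gain.realized_gain:.4f}",
            f"expected_gain: {self.gain.expected_gain:.4f}",
            f"max_expected_gain: {self.gain.meg:.4f}",
            f"gain_deficit: {self.gain.deficit:.6f}",
            f"near_side_preference: "
            + ("undefined" if self.near_side is None else f"{self.near_side:.4f}"),
            f"lrt_statistic: {self.lrt.statistic:.4f}",
            f"lrt_df: {self.lrt.df}",
            f"lrt_p_value: {self.lrt.p_value:.6g}",
            f"optimal_rate_overall: {self.repeated.overall_rate:.4f}",
            f"optimal_rate_repeated: {self.repeated.repeated_rate:.4f}",
        ]
        return "\n".join(lines) + "\n"


def analyze_session(
    trials: Sequence[DecisionTrial],
    prediction: StrategyPrediction,
    *,
    params: PsychometricParams | None = None,
    family: SizeSensitivityFamily | None = None,
    geometry: TaskGeometry | None = None,
    gain_model: GainModel = GainModel(),
    landing_criterion_radius: float = 1.0,
    side_separation: float | None = None,
) -> SessionReport:
    """Run the full analysis pipeline on one session's trial table."""
    retained, tally = apply_exclusions(
        trials, landing_criterion_radius, side_separation=side_separation
    )
    classified = classify_trials(retained, prediction, side_separation=side_separation)
    props = strategy_proportions(classified, prediction)
    gain = realized_gain_and_deficit(
        classified,
        prediction,
        params=params,
        family=family,
        geometry=geometry,
        gain_model=gain_model,
    )
    try:
        near = near_side_preference(classified)
    except InsufficientDataError:
        near = None
    dep = intertrial_dependency(classified)
    rep = repeated_condition_optimality(classified)
    lrt = nested_lrt_vs_meg(
        classified,
        prediction,
        params=params,
        family=family,
        geometry=geometry,
        gain_model=gain_model,
    )
    return SessionReport(
        proportions=props,
        switch_point=prediction.switch_point,
        variable=prediction.variable,
        gain=gain,
        near_side=near,
        dependency=dep,
        repeated=rep,
        lrt=lrt,
        exclusions=tally,
        n_retained=len(classified),
    )
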