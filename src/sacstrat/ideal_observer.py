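"""Strategy success probabilities, optimal switch points and expected gain.

In the three-token task the observer makes a single saccade before the
target appears, to either the center token or one of the two side tokens.
With side-token separation D (degrees) and the fixation placed equidistant
from the center and the nearer side token, the post-saccadic eccentricity
of the target is

* center strategy: D/2 whichever side the target appears on, so
  P[correct | center] = psi(D/2);
* side strategy: 0 if the target appears on the chosen side (probability w,
  0.5 for a symmetric prior) and D otherwise, so
  P[correct | side] = w * psi(0) + (1 - w) * psi(D).

The optimal switch point is the separation (or, in the size experiment, the
token size) at which the two strategies succeed equally often; the ideal
policy is a step function through it.  Roots are located by a fine bracket
scan plus Brent's method, and uniqueness on the search interval is checked
explicitly rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize

from .errors import (
    AmbiguousSwitchPointError,
    DomainError,
    NoSwitchPointError,
    UnknownConditionError,
)
from .psychometric import (
    PsychometricParams,
    SizeSensitivityFamily,
    evaluate_sensitivity,
    evaluate_size_sensitivity,
)

__all__ = [
    "TaskGeometry",
    "GainModel",
    "StrategyPrediction",
    "p_correct_center",
    "p_correct_side",
    "strategy_probabilities",
    "optimal_switch_separation",
    "optimal_switch_size",
    "make_step_policy",
    "expected_gain",
    "max_expected_gain",
]

ROOT_TOL = 1e-4  # degrees
SCAN_STEP = 0.01  # degrees, resolution of the uniqueness scan


@dataclass(frozen=True)
class TaskGeometry:
    """Token layout and fixation placement for one separation condition.

    Tokens sit on a horizontal row (y = 0) at x = -D/2, 0, +D/2.  The
    fixation cross sits ``vertical_offset`` degrees off that row, shifted
    D/4 toward ``fixation_side`` so that it is exactly equidistant from the
    center token and the nearer side token.
    """

    side_separation: float
    token_size: float = 1.0
    vertical_offset: float = 4.0
    fixation_side: str = "right"

    def __post_init__(self):
        if self.side_separation < 0:
            raise DomainError("side separation must be non-negative")
        if self.fixation_side not in ("left", "right"):
            raise DomainError("fixation_side must be 'left' or 'right'")

    @property
    def token_positions(self) -> dict[str, tuple[float, float]]:
        d = self.side_separation
        return {
            "left": (-d / 2.0, 0.0),
            "center": (0.0, 0.0),
            "right": (d / 2.0, 0.0),
        }

    @property
    def fixation_position(self) -> tuple[float, float]:
        sign = 1.0 if self.fixation_side == "right" else -1.0
        return (sign * self.side_separation / 4.0, -self.vertical_offset)

    @property
    def near_side(self) -> str:
        return self.fixation_side


@dataclass(frozen=True)
class GainModel:
    """Reward per correct response and the prior on target side."""

    reward_per_correct: float = 1.0
    p_target_left: float = 0.5

    def __post_init__(self):
        if self.reward_per_correct <= 0:
            raise DomainError("reward_per_correct must be positive")
        if not (0.0 < self.p_target_left < 1.0):
            raise DomainError("p_target_left must lie in (0, 1)")


@dataclass(frozen=True)
class StrategyPrediction:
    """An optimal switch point and the step policy it implies.

    ``variable`` says whether the policy steps in side-token separation
    (side above the switch point) or token size (side below it).
    """

    switch_point: float
    variable: Literal["separation", "size"]
    policy: Mapping[float, str]
    uniqueness_verified: bool

    def strategy_for(self, condition: float) -> str:
        for value, strat in self.policy.items():
            if np.isclose(value, condition, atol=1e-9):
                return strat
        raise UnknownConditionError(
            f"condition {condition} has no entry in the prediction policy"
        )

    def optimal_strategy(self, condition: float) -> str:
        """The ideal strategy for an arbitrary condition value (not limited
        to the tabulated policy)."""
        if self.variable == "separation":
            return "center" if condition < self.switch_point else "side"
        return "side" if condition < self.switch_point else "center"


def p_correct_center(params: PsychometricParams, geometry: TaskGeometry) -> float:
    """Probability of a correct discrimination under the center strategy: psi(D/2)."""
    return float(evaluate_sensitivity(params, geometry.side_separation / 2.0))


def p_correct_side(
    params: PsychometricParams,
    geometry: TaskGeometry,
    gain_model: GainModel = GainModel(),
) -> float:
    """Probability correct under the side strategy: w*psi(0) + (1-w)*psi(D),
    with w the probability the target lands on the chosen side."""
    w = (
        gain_model.p_target_left
        if geometry.near_side == "left"
        else 1.0 - gain_model.p_target_left
    )
    d = geometry.side_separation
    return float(
        w * evaluate_sensitivity(params, 0.0)
        + (1.0 - w) * evaluate_sensitivity(params, d)
    )


def strategy_probabilities(
    condition: float,
    *,
    variable: Literal["separation", "size"],
    params: PsychometricParams | None = None,
    family: SizeSensitivityFamily | None = None,
    geometry: TaskGeometry | None = None,
    gain_model: GainModel = GainModel(),
) -> tuple[float, float]:
    """(P[correct|center], P[correct|side]) at one condition value.

    For ``variable='separation'`` the condition is the side-token
    separation D and ``params`` supplies psi(E).  For ``variable='size'``
    the condition is the token size, the separation is fixed by
    ``geometry`` and ``family`` supplies psi_E(S) at E in {0, D/2, D}.
    """
    w = 0.5  # symmetric prior; side choice is whichever token the observer picks
    if variable == "separation":
        if params is None:
            raise ValueError("separation variant requires psi params")
        geo = TaskGeometry(side_separation=condition)
        return (
            p_correct_center(params, geo),
            p_correct_side(params, geo, gain_model),
        )
    if variable == "size":
        if family is None or geometry is None:
            raise ValueError("size variant requires a family and geometry")
        d = geometry.side_separation
        pc = evaluate_size_sensitivity(family, d / 2.0, condition)
        ps = w * evaluate_size_sensitivity(family, 0.0, condition) + (
            1.0 - w
        ) * evaluate_size_sensitivity(family, d, condition)
        return float(pc), float(ps)
    raise ValueError(f"unknown variable {variable!r}")


def _locate_unique_root(
    diff: Callable[[float], float], interval: tuple[float, float]
) -> tuple[float, bool]:
    lo, hi = interval
    if not (0 < lo < hi):
        raise DomainError("search interval must satisfy 0 < lo < hi")
    grid = np.arange(lo, hi + SCAN_STEP, SCAN_STEP)
    grid[-1] = min(grid[-1], hi)
    vals = np.array([diff(x) for x in grid])
    sign = np.sign(vals)
    # Treat exact zeros as part of the adjacent crossing.
    nz = sign != 0
    crossings = np.where(np.diff(sign[nz]) != 0)[0]
    idx = np.arange(len(grid))[nz]
    if len(crossings) == 0:
        raise NoSwitchPointError(
            f"strategies do not cross on [{lo}, {hi}]; no switch point exists"
        )
    if len(crossings) > 1:
        raise AmbiguousSwitchPointError(
            f"{len(crossings)} strategy crossings found on [{lo}, {hi}]"
        )
    a, b = grid[idx[crossings[0]]], grid[idx[crossings[0] + 1]]
    root = optimize.brentq(diff, a, b, xtol=ROOT_TOL)
    return float(root), True


def make_step_policy(
    conditions: Sequence[float],
    switch_point: float,
    variable: Literal["separation", "size"],
) -> dict[float, str]:
    """The ideal step policy over a condition list: for separations, center
    below the switch point and side above; reversed for sizes (large tokens
    are discriminable from the center token)."""
    policy = {}
    for c in conditions:
        if variable == "separation":
            policy[float(c)] = "center" if c < switch_point else "side"
        else:
            policy[float(c)] = "side" if c < switch_point else "center"
    return policy


def optimal_switch_separation(
    params: PsychometricParams,
    search_interval: tuple[float, float] = (0.5, 40.0),
    gain_model: GainModel = GainModel(),
    conditions: Sequence[float] = (),
) -> StrategyPrediction:
    """Separation at which center and side strategies succeed equally often.

    Solves psi(D/2) = w*psi(0) + (1-w)*psi(D) for D by bracket scan (0.01
    degree resolution) plus Brent refinement to 1e-4 degrees.  The interval
    must exclude 0 (where the equation holds trivially); multiple crossings
    raise instead of silently returning one root.
    """

    def diff(d: float) -> float:
        geo = TaskGeometry(side_separation=d)
        return p_correct_center(params, geo) - p_correct_side(params, geo, gain_model)

    root, unique = _locate_unique_root(diff, search_interval)
    return StrategyPrediction(
        switch_point=root,
        variable="separation",
        policy=make_step_policy(conditions, root, "separation"),
        uniqueness_verified=unique,
    )


def optimal_switch_size(
    family: SizeSensitivityFamily,
    geometry: TaskGeometry,
    search_interval: tuple[float, float] = (0.1, 5.0),
    conditions: Sequence[float] = (),
) -> StrategyPrediction:
    """Token size at which the strategies tie, at fixed separation D.

    Solves psi_{D/2}(S) = 0.5*psi_0(S) + 0.5*psi_D(S) for S.  The family
    must contain members at eccentricities {0, D/2, D}.
    """
    d = geometry.side_separation
    # Raises UnsupportedEccentricityError if a required member is missing.
    for ecc in (0.0, d / 2.0, d):
        family.member(ecc)

    def diff(s: float) -> float:
        pc, ps = strategy_probabilities(
            s, variable="size", family=family, geometry=geometry
        )
        return pc - ps

    root, unique = _locate_unique_root(diff, search_interval)
    return StrategyPrediction(
        switch_point=root,
        variable="size",
        policy=make_step_policy(conditions, root, "size"),
        uniqueness_verified=unique,
    )


def _condition_probs(
    condition: float,
    variable: str,
    params,
    family,
    geometry,
    gain_model,
) -> tuple[float, float]:
    return strategy_probabilities(
        condition,
        variable=variable,  # type: ignore[arg-type]
        params=params,
        family=family,
        geometry=geometry,
        gain_model=gain_model,
    )


def expected_gain(
    policy: Mapping[float, str],
    conditions: Sequence[tuple[float, int]],
    *,
    variable: Literal["separation", "size"] = "separation",
    params: PsychometricParams | None = None,
    family: SizeSensitivityFamily | None = None,
    geometry: TaskGeometry | None = None,
    gain_model: GainModel = GainModel(),
) -> float:
    """Expected winnings of a fixed policy over a schedule of conditions:
    sum over conditions of trials x reward x P[correct | chosen strategy]."""
    total = 0.0
    for value, count in conditions:
        strat = None
        for pv, ps in policy.items():
            if np.isclose(pv, value, atol=1e-9):
                strat = ps
                break
        if strat is None:
            raise UnknownConditionError(f"condition {value} missing from policy")
        pc, psd = _condition_probs(value, variable, params, family, geometry, gain_model)
        p = pc if strat == "center" else psd
        total += count * gain_model.reward_per_correct * p
    return total


def max_expected_gain(
    conditions: Sequence[tuple[float, int]],
    *,
    variable: Literal["separation", "size"] = "separation",
    params: PsychometricParams | None = None,
    family: SizeSensitivityFamily | None = None,
    geometry: TaskGeometry | None = None,
    gain_model: GainModel = GainModel(),
) -> tuple[float, dict[float, str]]:
    """Maximum expected gain (MEG) and the per-condition argmax policy."""
    policy = {}
    total = 0.0
    for value, count in conditions:
        pc, psd = _condition_probs(value, variable, params, family, geometry, gain_model)
        if pc >= psd:
            policy[float(value)] = "center"
            total += count * gain_model.reward_per_correct * pc
        else:
            policy[float(value)] = "side"
            total += count * gain_model.reward_per_correct * psd
    return total, policy
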