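"""Retinal sensitivity functions and their fits.

Discrimination performance in a two-alternative forced-choice task falls
from near-perfect at the fovea to chance (0.5) in the far periphery.  This
module represents that fall-off with a four-parameter logistic psychometric
function

    psi(E) = beta + (alpha - beta) / (1 + exp((E - e_half) / gamma))

where ``E`` is retinal eccentricity in degrees of visual angle, ``alpha``
is performance at the fovea, ``beta`` the asymptote at large eccentricity,
``e_half`` the eccentricity of the midpoint psi = (alpha + beta) / 2 (the
75%-correct point when alpha ~ 1 and beta ~ 0.5), and ``gamma > 0`` the
slope scale.  The same family, mirrored to be increasing, describes
sensitivity as a function of token *size* at a fixed eccentricity.

Fits are available by least squares on per-condition proportions correct
(the default) or by Bernoulli maximum likelihood, both with seeded
multi-start L-BFGS-B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, special

from .errors import (
    DomainError,
    FitConvergenceError,
    InsufficientDataError,
    UnsupportedEccentricityError,
)

__all__ = [
    "PsychometricParams",
    "SizeSensitivityFamily",
    "MappingTrial",
    "FitResult",
    "evaluate_sensitivity",
    "evaluate_size_sensitivity",
    "fit_sensitivity",
    "fit_size_family",
]

# Fitting bounds: chance floor is 0.5 for a 2AFC judgment.
_BOUNDS = {
    "alpha": (0.5, 1.0),
    "beta": (0.5, 1.0),
    "location": (1e-3, 40.0),
    "gamma": (1e-3, 20.0),
}
_DEGENERACY_GAP = 0.02  # alpha - beta below this flags a flat (chance) fit


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the four-parameter logistic sensitivity function.

    ``e_half`` doubles as the size-midpoint when the same parameter set
    describes an increasing size-sensitivity member (see
    :func:`evaluate_size_sensitivity`).
    """

    alpha: float
    beta: float
    e_half: float
    gamma: float

    def __post_init__(self):
        if not (0.0 <= self.beta <= self.alpha <= 1.0):
            raise DomainError(
                f"require 0 <= beta <= alpha <= 1, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.gamma <= 0:
            raise DomainError(f"gamma must be > 0, got {self.gamma}")
        if self.e_half <= 0:
            raise DomainError(f"e_half must be > 0, got {self.e_half}")

    def __call__(self, eccentricity):
        return evaluate_sensitivity(self, eccentricity)


@dataclass(frozen=True)
class MappingTrial:
    """One sensitivity-mapping trial: a target at a known eccentricity/size,
    a dot-up/dot-down configuration and the observer's judgment."""

    eccentricity: float
    size: float
    side: str  # "left" | "right"
    configuration: str  # "dot-up" | "dot-down"
    response: str | None = None
    observer: str = "sim"
    experiment: int = 1

    @property
    def correct(self) -> bool | None:
        if self.response is None:
            return None
        return self.response == self.configuration


@dataclass(frozen=True)
class FitResult:
    """A fitted sensitivity function plus fit diagnostics."""

    params: PsychometricParams
    method: str
    objective: float
    converged: bool
    degenerate: bool
    n_trials: int

    def __call__(self, eccentricity):
        return evaluate_sensitivity(self.params, eccentricity)

    def to_text(self) -> str:
        p = self.params
        lines = [
            f"alpha: {p.alpha:.6f}",
            f"beta: {p.beta:.6f}",
            f"e_half: {p.e_half:.6f}",
            f"gamma: {p.gamma:.6f}",
            f"method: {self.method}",
            f"objective: {self.objective:.10g}",
            f"converged: {self.converged}",
            f"degenerate: {self.degenerate}",
            f"n_trials: {self.n_trials}",
        ]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SizeSensitivityFamily:
    """Per-eccentricity sensitivity-in-size functions psi_E(S).

    Members are fit independently at each measured eccentricity; no
    interpolation across eccentricities is ever performed.
    """

    entries: tuple[tuple[float, PsychometricParams], ...]

    def __post_init__(self):
        eccs = [e for e, _ in self.entries]
        if len(set(eccs)) != len(eccs):
            raise DomainError("family eccentricities must be distinct")
        if any(e < 0 for e in eccs):
            raise DomainError("family eccentricities must be non-negative")

    @property
    def eccentricities(self) -> tuple[float, ...]:
        return tuple(e for e, _ in self.entries)

    def member(self, eccentricity: float) -> PsychometricParams:
        for e, p in self.entries:
            if np.isclose(e, eccentricity, atol=1e-9):
                return p
        raise UnsupportedEccentricityError(
            f"no sensitivity member at eccentricity {eccentricity}; "
            f"measured eccentricities are {self.eccentricities}"
        )

    def __call__(self, eccentricity: float, size) -> float:
        return evaluate_size_sensitivity(self, eccentricity, size)


def evaluate_sensitivity(params: PsychometricParams, eccentricity) -> float | np.ndarray:
    """psi(E): probability of correct discrimination at eccentricity E (degrees).

    Non-increasing in E, bounded in [beta, alpha]; errors on negative E.
    """
    e = np.asarray(eccentricity, dtype=float)
    if np.any(e < 0):
        raise DomainError("eccentricity must be non-negative")
    val = params.beta + (params.alpha - params.beta) * special.expit(
        -(e - params.e_half) / params.gamma
    )
    return float(val) if np.isscalar(eccentricity) else val


def _evaluate_size_member(params: PsychometricParams, size) -> float | np.ndarray:
    # Mirror image of the eccentricity logistic: non-decreasing in size.
    s = np.asarray(size, dtype=float)
    if np.any(s < 0):
        raise DomainError("size must be non-negative")
    val = params.beta + (params.alpha - params.beta) * special.expit(
        (s - params.e_half) / params.gamma
    )
    return float(val) if np.isscalar(size) else val


def evaluate_size_sensitivity(
    family: SizeSensitivityFamily, eccentricity: float, size
) -> float | np.ndarray:
    """psi_E(S): discrimination probability for a token of ``size`` degrees viewed
    at one of the family's measured eccentricities.  No interpolation: an
    unmeasured eccentricity raises :class:`UnsupportedEccentricityError`."""
    return _evaluate_size_member(family.member(eccentricity), size)


def _aggregate(trials: Iterable[MappingTrial], key: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse trials to (level, n, k) triples keyed by eccentricity or size."""
    counts: dict[float, list[int]] = {}
    for t in trials:
        if t.response is None:
            continue
        level = getattr(t, key)
        n_k = counts.setdefault(float(level), [0, 0])
        n_k[0] += 1
        n_k[1] += int(t.correct)
    levels = np.array(sorted(counts))
    n = np.array([counts[lv][0] for lv in levels], dtype=float)
    k = np.array([counts[lv][1] for lv in levels], dtype=float)
    return levels, n, k


def _logistic(x, theta, increasing: bool):
    alpha, beta, loc, gamma = theta
    z = (x - loc) / gamma
    if increasing:
        z = -z
    return beta + (alpha - beta) * special.expit(-z)


def _fit_logistic(
    levels: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    method: str,
    increasing: bool,
    seed: int,
    n_starts: int,
) -> FitResult:
    phat = k / n

    if method == "least-squares":
        def objective(theta):
            pred = _logistic(levels, theta, increasing)
            penalty = 1e3 * max(0.0, theta[1] - theta[0]) ** 2
            return float(np.sum((phat - pred) ** 2)) + penalty
    elif method == "max-likelihood":
        def objective(theta):
            pred = np.clip(_logistic(levels, theta, increasing), 1e-9, 1 - 1e-9)
            nll = -float(np.sum(k * np.log(pred) + (n - k) * np.log(1 - pred)))
            penalty = 1e3 * max(0.0, theta[1] - theta[0]) ** 2
            return nll + penalty
    else:
        raise ValueError(f"unknown fit method {method!r}")

    lo = np.array([b[0] for b in _BOUNDS.values()])
    hi = np.array([b[1] for b in _BOUNDS.values()])
    rng = np.random.default_rng(seed)
    span = float(levels.max() - levels.min()) or 1.0

    # First start from data-driven guesses, remaining starts random in bounds.
    guesses = [
        np.array([
            min(max(phat.max(), 0.51), 1.0),
            min(max(phat.min(), 0.5), 0.99),
            float(np.median(levels)) if np.median(levels) > 0 else span / 2,
            span / 4,
        ])
    ]
    for _ in range(n_starts - 1):
        guesses.append(lo + rng.random(4) * (hi - lo))

    best = None
    diagnostics = []
    for x0 in guesses:
        x0 = np.clip(x0, lo, hi)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=list(zip(lo, hi))
        )
        diagnostics.append((res.success, float(res.fun), res.message))
        if not res.success:
            continue
        if (
            best is None
            or res.fun < best.fun - 1e-12
            or (abs(res.fun - best.fun) <= 1e-12 and res.x[2] < best.x[2])
        ):
            best = res
    if best is None:
        raise FitConvergenceError(
            f"{method} sensitivity fit failed to converge from {n_starts} starts",
            diagnostics,
        )

    alpha, beta, loc, gamma = best.x
    beta = min(beta, alpha)  # penalty makes violations negligible; clamp residual
    params = PsychometricParams(alpha=alpha, beta=beta, e_half=loc, gamma=gamma)
    return FitResult(
        params=params,
        method=method,
        objective=float(best.fun),
        converged=True,
        degenerate=(alpha - beta) < _DEGENERACY_GAP,
        n_trials=int(n.sum()),
    )


def fit_sensitivity(
    trials: Sequence[MappingTrial],
    method: Literal["least-squares", "max-likelihood"] = "least-squares",
    *,
    seed: int = 0,
    n_starts: int = 10,
) -> FitResult:
    """Fit psi(E) to mapping trials.

    Requires >= 3 distinct eccentricities.  ``least-squares`` minimizes the
    squared error between psi and the per-eccentricity proportion correct;
    ``max-likelihood`` maximizes the Bernoulli likelihood of the raw trials.
    Multi-start optimization (seeded) guards against local minima; ties go
    to the smallest midpoint.  A flat fit (alpha ~ beta) is returned with
    ``degenerate=True`` rather than raising.
    """
    levels, n, k = _aggregate(trials, "eccentricity")
    if len(levels) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct eccentricities, got {len(levels)}"
        )
    return _fit_logistic(levels, n, k, method, increasing=False, seed=seed, n_starts=n_starts)


def fit_size_family(
    trials: Sequence[MappingTrial],
    method: Literal["least-squares", "max-likelihood"] = "least-squares",
    *,
    seed: int = 0,
    n_starts: int = 10,
) -> SizeSensitivityFamily:
    """Fit one sensitivity-in-size function per measured eccentricity.

    Requires >= 2 distinct eccentricities with >= 3 distinct sizes each.
    """
    by_ecc: dict[float, list[MappingTrial]] = {}
    for t in trials:
        by_ecc.setdefault(float(t.eccentricity), []).append(t)
    if len(by_ecc) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct eccentricities for a size family, got {len(by_ecc)}"
        )
    entries = []
    for i, ecc in enumerate(sorted(by_ecc)):
        levels, n, k = _aggregate(by_ecc[ecc], "size")
        if len(levels) < 3:
            raise InsufficientDataError(
                f"eccentricity {ecc}: need >= 3 distinct sizes, got {len(levels)}"
            )
        fit = _fit_logistic(
            levels, n, k, method, increasing=True, seed=seed + i, n_starts=n_starts
        )
        entries.append((ecc, fit.params))
    return SizeSensitivityFamily(entries=tuple(entries))
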