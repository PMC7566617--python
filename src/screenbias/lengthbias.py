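"""Two-subtype length-bias correction of the screening survival advantage.

Length bias arises because slowly progressing tumours spend longer in the
preclinical screen-detectable phase and are therefore over-represented
among screen-detected cases. The model posits a non-aggressive subtype
that is both more likely to be screen-detected and less lethal, governed by
a single factor ``theta`` in (0, 1]:

* non-aggressive 5-year case fatality = ``theta`` x aggressive fatality;
* aggressive screen-detection probability = ``theta`` x non-aggressive.

Given the observed crude inputs ``p1`` (5-year case fatality, symptomatic
cases), ``p2`` (same, screen-detected cases) and ``p3`` (screened fraction
of the cohort), and a hypothesised subtype mix ``q`` (aggressive
proportion), the solver recovers:

* ``s``     non-aggressive screen-detection probability, from ``p3``;
* ``delta`` aggressive symptomatic 5-year fatality, from ``p1``;
* ``psi``   the corrected relative hazard of death for screen-detected vs
  symptomatic cases net of length bias, by root-finding from ``p2`` under
  exponential within-subtype survival (screen-detection multiplies the
  within-subtype hazard by ``psi``, so a within-horizon fatality ``p``
  becomes ``1 - (1-p)**psi``);
* ``phi``   the corrected relative risk on the probability scale.

Combinations of (q, theta) for which ``s`` or ``delta`` leaves (0, 1] or no
root exists are reported as explicit no-solution cells — the blank region
of the corrected-hazard surface. The nullification factor is the smallest
fold-difference ``1/theta`` at which the corrected hazard reaches 1, i.e.
at which length bias alone could explain the whole observed advantage.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ObservedFatalities", "SubtypeModel", "LengthBiasSurface",
           "uncorrected_relative_hazard", "solve_subtype_model",
           "corrected_hazard_surface", "nullification_factor",
           "NullificationResult"]

PSI_BRACKET = (1e-6, 10.0)

# no-solution status codes
OK = "ok"
NO_SOLUTION_S = "s_out_of_range"
NO_SOLUTION_DELTA = "delta_out_of_range"
NO_SOLUTION_ROOT = "no_root"
PSI_ABOVE_BRACKET = "psi_above_bracket"


@dataclasses.dataclass(frozen=True)
class ObservedFatalities:
    """Observed crude inputs of the length-bias correction."""
    p1: float                   # 5-year case fatality, symptomatic cases
    p2: float                   # 5-year case fatality, screen-detected cases
    p3: float                   # screened fraction of the cohort
    horizon_years: float = 5.0

    def __post_init__(self):
        for name in ("p1", "p2", "p3"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.degenerate:
            warnings.warn("degenerate fatality inputs (0 or 1): downstream "
                          "corrections are undefined", stacklevel=2)
        elif self.p2 >= self.p1:
            warnings.warn("p2 >= p1: screen-detected cases show no crude "
                          "survival advantage", stacklevel=2)

    @property
    def degenerate(self) -> bool:
        """True when any input sits on the boundary of (0, 1)."""
        return any(getattr(self, n) in (0.0, 1.0) for n in ("p1", "p2", "p3"))

    @classmethod
    def from_counts(cls, symptomatic_deaths: int, symptomatic_n: int,
                    screened_deaths: int, screened_n: int, cohort_n: int,
                    horizon_years: float = 5.0) -> "ObservedFatalities":
        return cls(p1=symptomatic_deaths / symptomatic_n,
                   p2=screened_deaths / screened_n,
                   p3=screened_n / cohort_n, horizon_years=horizon_years)


@dataclasses.dataclass(frozen=True)
class SubtypeModel:
    """Solved subtype parameters for one (q, theta) cell."""
    q: float
    theta: float
    s: float | None
    delta: float | None
    psi: float | None           # corrected relative hazard
    phi: float | None           # corrected relative risk
    status: str

    @property
    def solved(self) -> bool:
        return self.status == OK


def uncorrected_relative_hazard(obs: ObservedFatalities) -> float:
    """Relative hazard implied by the crude fatalities under exponential
    survival: ``ln(1-p2)/ln(1-p1)`` (< 1 iff p2 < p1; horizon cancels)."""
    if not 0 < obs.p1 < 1 or not 0 < obs.p2 < 1:
        raise ValueError("p1 and p2 must lie strictly inside (0, 1)")
    return math.log1p(-obs.p2) / math.log1p(-obs.p1)


def _p2_model(psi: float, q: float, theta: float, delta: float) -> float:
    """Screen-detected crude fatality implied by the subtype mixture at
    within-subtype hazard ratio ``psi``."""
    w_agg = q * theta           # detection-weighted aggressive share
    w_non = 1.0 - q
    f_agg = 1.0 - (1.0 - delta) ** psi
    f_non = 1.0 - (1.0 - theta * delta) ** psi
    return (w_agg * f_agg + w_non * f_non) / (w_agg + w_non)


def solve_subtype_model(obs: ObservedFatalities, q: float, theta: float,
                        scale: str = "hazard") -> SubtypeModel:
    """Solve the subtype mixture for one (q, theta) combination.

    ``scale='hazard'`` (default) defines psi on the within-subtype hazard
    scale through the exponential-survival transform; ``scale='risk'``
    reports the risk-scale correction (psi = phi) instead.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if not 0 < theta <= 1:
        raise ValueError(f"theta must lie in (0, 1], got {theta}")
    if scale not in ("hazard", "risk"):
        raise ValueError("scale must be 'hazard' or 'risk'")

    mix = q * theta + (1.0 - q)
    s = obs.p3 / mix
    if not 0 < s <= 1 or not 0 < theta * s <= 1:
        return SubtypeModel(q, theta, None, None, None, None, NO_SOLUTION_S)

    a = q * (1.0 - theta * s)        # aggressive share among symptomatic
    b = (1.0 - q) * (1.0 - s)        # non-aggressive share among symptomatic
    if a + b <= 0:
        return SubtypeModel(q, theta, s, None, None, None, NO_SOLUTION_DELTA)
    delta = obs.p1 * (a + b) / (a + b * theta)
    if not 0 < delta <= 1:
        return SubtypeModel(q, theta, s, delta, None, None, NO_SOLUTION_DELTA)

    phi = obs.p2 * mix / (theta * delta)

    def f(psi):
        return _p2_model(psi, q, theta, delta) - obs.p2

    lo, hi = PSI_BRACKET
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0:
        return SubtypeModel(q, theta, s, delta, None, phi, NO_SOLUTION_ROOT)
    if f_hi < 0:
        return SubtypeModel(q, theta, s, delta, None, phi, PSI_ABOVE_BRACKET)
    psi = float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))

    # mandatory internal consistency check: back-substitution reproduces
    # (p1, p2, p3) to 1e-8
    p3_back = s * mix
    p1_back = delta * (a + b * theta) / (a + b)
    p2_back = _p2_model(psi, q, theta, delta)
    resid = max(abs(p3_back - obs.p3), abs(p1_back - obs.p1),
                abs(p2_back - obs.p2))
    if resid > 1e-8:  # pragma: no cover - guards formula regressions
        raise AssertionError(
            f"back-substitution failed at (q={q}, theta={theta}): residual {resid:g}")

    psi_out = psi if scale == "hazard" else phi
    return SubtypeModel(q, theta, s, delta, psi_out, phi, OK)


@dataclasses.dataclass
class LengthBiasSurface:
    """Corrected relative hazard / risk over a (q, theta) grid.

    ``psi``/``phi`` are ``len(q_grid) x len(theta_grid)`` arrays with NaN in
    no-solution cells; ``status`` carries the per-cell code. The theta = 1
    column, where defined, equals the uncorrected relative hazard.
    """
    q_grid: np.ndarray
    theta_grid: np.ndarray
    psi: np.ndarray
    phi: np.ndarray
    status: np.ndarray
    uncorrected: float

    @property
    def n_unsolved(self) -> int:
        return int(np.sum(self.status != OK))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, q in enumerate(self.q_grid):
            for j, th in enumerate(self.theta_grid):
                rows.append({"q": q, "theta": th, "psi": self.psi[i, j],
                             "phi": self.phi[i, j],
                             "status": self.status[i, j]})
        return pd.DataFrame(rows)


def corrected_hazard_surface(obs: ObservedFatalities, q_grid, theta_grid,
                             scale: str = "hazard") -> LengthBiasSurface:
    """Cell-wise subtype solve over the (q, theta) grid (deterministic)."""
    q_grid = np.asarray(q_grid, dtype=float)
    theta_grid = np.asarray(theta_grid, dtype=float)
    psi = np.full((q_grid.size, theta_grid.size), np.nan)
    phi = np.full_like(psi, np.nan)
    status = np.full(psi.shape, "", dtype=object)
    for i, q in enumerate(q_grid):
        for j, th in enumerate(theta_grid):
            sol = solve_subtype_model(obs, float(q), float(th), scale=scale)
            status[i, j] = sol.status
            if sol.solved:
                psi[i, j] = sol.psi
                phi[i, j] = sol.phi
    return LengthBiasSurface(q_grid, theta_grid, psi, phi, status,
                             uncorrected=uncorrected_relative_hazard(obs))


@dataclasses.dataclass(frozen=True)
class NullificationResult:
    """Fold-difference required for length bias to nullify the advantage."""
    k: float                    # 1/theta*; inf when not nullifiable
    theta_star: float | None
    q_star: float | None
    nullifiable: bool


def _max_psi_over_q(obs: ObservedFatalities, theta: float,
                    n_grid: int = 199) -> tuple[float, float]:
    """Maximum corrected hazard over q in (0,1) at fixed theta."""
    qs = np.linspace(0.005, 0.995, n_grid)
    best_psi, best_q = -np.inf, np.nan
    for q in qs:
        sol = solve_subtype_model(obs, float(q), theta)
        if sol.solved and sol.psi > best_psi:
            best_psi, best_q = sol.psi, float(q)
    if not np.isfinite(best_psi):
        return -np.inf, np.nan
    lo = max(best_q - 1.5 / n_grid, 1e-4)
    hi = min(best_q + 1.5 / n_grid, 1 - 1e-4)

    def neg(q):
        sol = solve_subtype_model(obs, float(q), theta)
        return -sol.psi if sol.solved else 1e300

    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    if np.isfinite(res.fun) and -res.fun > best_psi:
        best_psi, best_q = -float(res.fun), float(res.x)
    return best_psi, best_q


def nullification_factor(obs: ObservedFatalities,
                         tol: float = 1e-4) -> NullificationResult:
    """Smallest fold-difference 1/theta at which the corrected hazard can
    reach 1 for some subtype mix q.

    Bisection on theta (the corrected hazard decreases in theta) with an
    inner maximisation over q; requires ``p2 < p1``. ``p1 == p2`` returns
    k = 1: the uncorrected ratio is already 1 and no bias is needed.
    """
    if obs.p2 > obs.p1:
        raise ValueError("nullification factor requires p2 <= p1")
    if obs.p1 == obs.p2:
        return NullificationResult(k=1.0, theta_star=1.0, q_star=None,
                                   nullifiable=True)

    # scan downwards for the bisection bracket
    hi = 1.0                      # max_psi(hi) < 1
    lo = None
    for theta in np.r_[np.linspace(0.9, 0.05, 18), 0.02, 0.01, 0.005, 0.002, 0.001]:
        m, _ = _max_psi_over_q(obs, float(theta))
        if m >= 1.0:
            lo = float(theta)
            break
        hi = float(theta)
    if lo is None:
        return NullificationResult(k=math.inf, theta_star=None, q_star=None,
                                   nullifiable=False)

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        m, _ = _max_psi_over_q(obs, mid)
        if m >= 1.0:
            lo = mid
        else:
            hi = mid
    theta_star = 0.5 * (lo + hi)
    _, q_star = _max_psi_over_q(obs, theta_star)
    return NullificationResult(k=1.0 / theta_star, theta_star=theta_star,
                               q_star=q_star, nullifiable=True)
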