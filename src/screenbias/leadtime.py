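"""Lead-time bias correction for screen-detected cases.

Screening advances the date of diagnosis without necessarily postponing
death, so observed survival of screen-detected cases is inflated by the
lead time. Two corrections are provided:

* a fixed stage-based subtraction (100 days for stages I-II, 30 days for
  stages III-IV), and
* the exponential-sojourn expected lead time
  ``E(s) = (1 - exp(-lambda t)) / lambda`` subtracted from each
  screen-detected case's observed time, with ``lambda`` (the per-year rate
  of transition from preclinical to symptomatic disease; mean sojourn time
  ``1/lambda``) drawn from a normal distribution, repeated over a Monte
  Carlo grid of (mean, SD) pairs with a Cox refit per replicate.

Survival times are stored in days and converted at 365.25 days/year; the
lambda grid 0.05-1.0 per year corresponds to mean sojourn times of 1-20
years. Corrected times are floored at 1 day rather than dropping records.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .survival import ModelSpec, build_design, fit_cox

__all__ = ["expected_lead_time", "apply_fixed_correction",
           "apply_sojourn_correction", "mc_lead_time_grid",
           "SojournSpec", "LeadTimeGridResult"]

DAYS_PER_YEAR = 365.25
FLOOR_DAYS = 1.0
_LAMBDA_FLOOR = 1e-6


def expected_lead_time(lambda_rate, t):
    """Expected lead time ``(1 - exp(-lambda t)) / lambda`` in years.

    ``lambda_rate`` is the per-year rate of transition to symptomatic
    disease, ``t`` the observed time in years. The value increases with
    ``t`` and is bounded by ``min(t, 1/lambda)``.
    """
    lam = np.asarray(lambda_rate, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda_rate must be positive")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = -np.expm1(-lam * t) / lam
    return out if out.ndim else float(out)


def apply_fixed_correction(cohort: pd.DataFrame):
    """Stage-based fixed lead-time subtraction for screened cases.

    Returns ``(corrected cohort, floored_count)``: screened cases lose 100
    days (stages I-II) or 30 days (stages III-IV); unscreened cases and
    event flags are untouched; corrected times are floored at 1 day.
    """
    out = cohort.copy()
    screened = out["screened"].astype(bool).to_numpy()
    early = out["stage"].isin(["I", "II"]).to_numpy()
    subtract = np.where(screened, np.where(early, 100.0, 30.0), 0.0)
    corrected = out["time_days"].to_numpy(dtype=float) - subtract
    floored = int(np.sum(screened & (corrected < FLOOR_DAYS)))
    out["time_days"] = np.maximum(corrected, FLOOR_DAYS)
    return out, floored


def apply_sojourn_correction(cohort: pd.DataFrame, lambda_draws):
    """Subtract the expected exponential-sojourn lead time per screened case.

    ``lambda_draws`` supplies one positive per-year rate per screened case,
    in cohort row order restricted to screened rows. Event and censored
    times are corrected alike; unscreened rows are untouched; corrected
    times are floored at 1 day and the floor count returned.
    """
    out = cohort.copy()
    screened = out["screened"].astype(bool).to_numpy()
    lam = np.asarray(lambda_draws, dtype=float)
    n_screened = int(screened.sum())
    if lam.shape[0] != n_screened:
        raise ValueError(
            f"need one lambda draw per screened case ({n_screened}), got {lam.shape[0]}")
    if n_screened == 0:
        return out, 0
    if np.any(lam <= 0):
        raise ValueError("lambda draws must be positive")
    t_years = out.loc[screened, "time_days"].to_numpy(dtype=float) / DAYS_PER_YEAR
    lead_days = expected_lead_time(lam, t_years) * DAYS_PER_YEAR
    corrected = out.loc[screened, "time_days"].to_numpy(dtype=float) - lead_days
    floored = int(np.sum(corrected < FLOOR_DAYS))
    time = out["time_days"].to_numpy(dtype=float).copy()
    time[screened] = np.maximum(corrected, FLOOR_DAYS)
    out["time_days"] = time
    return out, floored


@dataclasses.dataclass(frozen=True)
class SojournSpec:
    """Monte Carlo sampling specification for the sojourn rate lambda."""
    replicates: int = 1000
    seed: int = 0
    per_case: bool = True   # one draw per screened case; False: one per replicate

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclasses.dataclass
class LeadTimeGridResult:
    """Per-cell outcome of the Monte Carlo lead-time grid.

    All per-cell arrays are indexed ``[i_mean, j_sd]``. ``p_gt_05_*`` is the
    fraction of replicates in which the Wald p-value of the named
    coefficient exceeded 0.05 after lead-time correction.
    """
    lambda_means: np.ndarray
    lambda_sds: np.ndarray
    replicates: int
    screen_coef: str
    region_coef: str
    p_gt_05_screen: np.ndarray
    p_gt_05_region: np.ndarray
    hr_screen_min: np.ndarray
    hr_screen_mean: np.ndarray
    hr_screen_max: np.ndarray
    hr_region_min: np.ndarray
    hr_region_mean: np.ndarray
    hr_region_max: np.ndarray
    nonconverged: np.ndarray
    uncorrected_hr_screen: float
    uncorrected_hr_region: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (mean, SD) cell."""
        rows = []
        for i, mu in enumerate(self.lambda_means):
            for j, sd in enumerate(self.lambda_sds):
                rows.append({
                    "lambda_mean": mu, "lambda_sd": sd,
                    "replicates": self.replicates,
                    "p_gt_05_screen": self.p_gt_05_screen[i, j],
                    "p_gt_05_region": self.p_gt_05_region[i, j],
                    "hr_screen_min": self.hr_screen_min[i, j],
                    "hr_screen_mean": self.hr_screen_mean[i, j],
                    "hr_screen_max": self.hr_screen_max[i, j],
                    "hr_region_min": self.hr_region_min[i, j],
                    "hr_region_mean": self.hr_region_mean[i, j],
                    "hr_region_max": self.hr_region_max[i, j],
                    "nonconverged": self.nonconverged[i, j],
                })
        return pd.DataFrame(rows)


def mc_lead_time_grid(cohort: pd.DataFrame, spec: ModelSpec,
                      lambda_means, lambda_sds,
                      sojourn: SojournSpec = SojournSpec(),
                      screen_coef: str = "screened",
                      region_coef: str = "region_XF",
                      ties: str = "efron") -> LeadTimeGridResult:
    """Monte Carlo lead-time correction over a (mean, SD) lambda grid.

    For each grid cell, ``sojourn.replicates`` replicates draw per-screened-
    case rates from Normal(mean, SD) truncated below at 1e-6, correct the
    screened survival times, refit the Cox model, and record Wald p-values
    and hazard ratios for the screening and region coefficients. Results
    are bit-reproducible from the seed and invariant to record order
    (draws are assigned to screened cases sorted by patient id).
    """
    lambda_means = np.asarray(lambda_means, dtype=float)
    lambda_sds = np.asarray(lambda_sds, dtype=float)
    X, names = build_design(cohort, spec)
    if screen_coef not in names or region_coef not in names:
        raise ValueError(
            f"model must contain {screen_coef!r} and {region_coef!r}; has {names}")
    time = cohort["time_days"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(bool)
    base = fit_cox(time, event, X, names=names, ties=ties)  # sanity fit + warm start
    js, jr = names.index(screen_coef), names.index(region_coef)

    screened_mask = cohort["screened"].astype(bool).to_numpy()
    screen_rows = np.flatnonzero(screened_mask)
    # stable case order for draw assignment, independent of row order
    screen_rows = screen_rows[np.argsort(cohort["id"].astype(str).to_numpy()[screen_rows],
                                         kind="stable")]
    n_screened = screen_rows.size

    shape = (lambda_means.size, lambda_sds.size)
    frac_s = np.zeros(shape)
    frac_r = np.zeros(shape)
    stats_hr = {k: np.zeros(shape) for k in
                ("s_min", "s_mean", "s_max", "r_min", "r_mean", "r_max")}
    nonconv = np.zeros(shape, dtype=int)

    t_years = time / DAYS_PER_YEAR
    for i, mu in enumerate(lambda_means):
        for j, sd in enumerate(lambda_sds):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(sojourn.seed), i, j]))
            hr_s = np.empty(sojourn.replicates)
            hr_r = np.empty(sojourn.replicates)
            p_s = np.empty(sojourn.replicates)
            p_r = np.empty(sojourn.replicates)
            for rep in range(sojourn.replicates):
                if sojourn.per_case:
                    lam = rng.normal(mu, sd, size=n_screened)
                else:
                    lam = np.full(n_screened, rng.normal(mu, sd))
                lam = np.maximum(lam, _LAMBDA_FLOOR)
                lead = expected_lead_time(lam, t_years[screen_rows]) * DAYS_PER_YEAR
                t_new = time.copy()
                t_new[screen_rows] = np.maximum(time[screen_rows] - lead, FLOOR_DAYS)
                fit = fit_cox(t_new, event, X, names=names, ties=ties,
                              beta0=base.beta, check_rank=False)
                if not fit.converged:
                    nonconv[i, j] += 1
                hr_s[rep], hr_r[rep] = fit.hr[js], fit.hr[jr]
                p_s[rep], p_r[rep] = fit.p[js], fit.p[jr]
            frac_s[i, j] = float(np.mean(p_s > 0.05))
            frac_r[i, j] = float(np.mean(p_r > 0.05))
            stats_hr["s_min"][i, j] = hr_s.min()
            stats_hr["s_mean"][i, j] = hr_s.mean()
            stats_hr["s_max"][i, j] = hr_s.max()
            stats_hr["r_min"][i, j] = hr_r.min()
            stats_hr["r_mean"][i, j] = hr_r.mean()
            stats_hr["r_max"][i, j] = hr_r.max()

    return LeadTimeGridResult(
        lambda_means=lambda_means, lambda_sds=lambda_sds,
        replicates=sojourn.replicates, screen_coef=screen_coef,
        region_coef=region_coef,
        p_gt_05_screen=frac_s, p_gt_05_region=frac_r,
        hr_screen_min=stats_hr["s_min"], hr_screen_mean=stats_hr["s_mean"],
        hr_screen_max=stats_hr["s_max"], hr_region_min=stats_hr["r_min"],
        hr_region_mean=stats_hr["r_mean"], hr_region_max=stats_hr["r_max"],
        nonconverged=nonconv,
        uncorrected_hr_screen=float(base.hr[js]),
        uncorrected_hr_region=float(base.hr[jr]))


def default_lambda_grid(lo: float = 0.05, hi: float = 1.0, step: float = 0.05):
    """The published grid: 0.05 to 1.0 per year on both axes (step 0.05)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)
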