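"""Survival machinery: Kaplan-Meier, log-rank, Cox regression, Schoenfeld.

The Cox partial-likelihood engine is implemented here as a vectorised
Newton-Raphson with Efron (default) or Breslow tie handling, step-halving,
warm starts and linear offsets. The Monte Carlo lead-time grid and the
shared-frailty EM both refit this model thousands of times, so the engine
avoids per-event Python loops entirely: risk-set sums are reverse cumulative
sums and tie groups are expanded with ``repeat``/``reduceat``.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines
behind this module's interface; Greenwood variances are derived from the
lifelines event table. Times are in days throughout.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "ModelSpec", "DEFAULT_MODEL_SPEC", "build_design",
    "KMCurve", "km_estimate", "LogrankResult", "logrank_test",
    "CoxFit", "fit_cox", "fit_cox_frame", "breslow_cumulative_hazard",
    "SchoenfeldResiduals", "schoenfeld_residuals",
    "RankDeficiencyError",
]


class RankDeficiencyError(ValueError):
    """Design matrix is not full rank; names the suspect columns."""


# ---------------------------------------------------------------------------
# Model specification / design encoding

@dataclasses.dataclass(frozen=True)
class Term:
    """One model term: a boolean column, a categorical with a reference
    level, or a threshold indicator on a continuous column."""
    kind: str                   # "binary" | "categorical" | "threshold"
    column: str
    reference: str | None = None
    threshold: float | None = None
    name: str | None = None


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate terms mapping a cohort frame to a design matrix."""
    terms: tuple

    def column_names(self, df: pd.DataFrame) -> list[str]:
        return build_design(df, self)[1]


def binary(column: str) -> Term:
    return Term("binary", column)


def categorical(column: str, reference: str) -> Term:
    return Term("categorical", column, reference=reference)


def threshold(column: str, cut: float, name: str) -> Term:
    return Term("threshold", column, threshold=cut, name=name)


#: The a-priori multivariate factor list with its reference levels
#: (reference: stage I, adenocarcinoma, normal BMI, female, non-Han).
DEFAULT_MODEL_SPEC = ModelSpec(terms=(
    threshold("age_years", 65.0, "age_gt65"),
    categorical("sex", reference="female"),
    categorical("ethnicity", reference="nonHan"),
    categorical("stage", reference="I"),
    categorical("histology", reference="adenocarcinoma"),
    categorical("bmi_category", reference="normal"),
    binary("cci_gt3"),
    binary("kps_gt70"),
    binary("smoker"),
    binary("surgery"),
    binary("chemo"),
    binary("radio"),
    binary("targeted"),
    categorical("region", reference="nonXF"),
    binary("screened"),
))

#: Reduced spec for simulation studies (matches the synthetic generator's
#: effect covariates).
SIM_MODEL_SPEC = ModelSpec(terms=(
    threshold("age_years", 65.0, "age_gt65"),
    categorical("sex", reference="female"),
    categorical("stage", reference="I"),
    binary("surgery"),
    categorical("region", reference="nonXF"),
    binary("screened"),
))


def build_design(df: pd.DataFrame, spec: ModelSpec,
                 drop_constant: bool = False) -> tuple[np.ndarray, list[str]]:
    """Reference-level dummy encoding of a cohort frame.

    With ``drop_constant=True`` columns without variation (e.g. an empty
    factor level in a subcohort) are dropped instead of raising later at the
    rank check.
    """
    cols, names = [], []
    for term in spec.terms:
        if term.kind == "binary":
            cols.append(df[term.column].astype(bool).to_numpy(dtype=float))
            names.append(term.name or term.column)
        elif term.kind == "threshold":
            cols.append((df[term.column].astype(float) > term.threshold)
                        .to_numpy(dtype=float))
            names.append(term.name or f"{term.column}_gt{term.threshold:g}")
        elif term.kind == "categorical":
            values = df[term.column].astype(str)
            levels = [l for l in sorted(values.unique()) if l != term.reference]
            for level in levels:
                cols.append((values == level).to_numpy(dtype=float))
                names.append(f"{term.column}_{level}")
        else:  # pragma: no cover
            raise ValueError(f"unknown term kind {term.kind!r}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    if drop_constant:
        keep = [j for j in range(X.shape[1]) if X[:, j].std() > 0]
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank (lifelines-backed)

@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance.

    ``median`` is the smallest time with survival <= 0.5, NaN when never
    reached.
    """
    times: np.ndarray           # distinct observed times, ascending
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int
    label: str | None = None

    @property
    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("nan")

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation at arbitrary horizons."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if np.ndim(t) else float(out[0])


def km_estimate(time, event, label: str | None = None) -> KMCurve:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("at least one sample required")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event, label=label or "KM")
    table = kmf.event_table
    table = table[table["removed"] > 0]  # drop the synthetic t=0 row
    times = table.index.to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    n_at_risk = table["at_risk"].to_numpy(dtype=float)
    frac = np.where(n_at_risk > 0, 1 - d / n_at_risk, 1.0)
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where((n_at_risk > d) & (n_at_risk > 0),
                       d / (n_at_risk * (n_at_risk - d)), 0.0)
    var = survival ** 2 * np.cumsum(inc)
    half = 1.959963984540054 * np.sqrt(var)
    return KMCurve(times=times, survival=survival, greenwood_var=var,
                   ci_low=np.clip(survival - half, 0, 1),
                   ci_high=np.clip(survival + half, 0, 1),
                   at_risk=n_at_risk, n=int(time.size),
                   n_events=int(event.sum()), label=label)


@dataclasses.dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def logrank_test(time, event, groups) -> LogrankResult:
    """K-sample log-rank test (chi-square with k-1 df)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(np.asarray(time, dtype=float), groups,
                                    np.asarray(event, dtype=bool))
    return LogrankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value), df=int(labels.size - 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards engine

def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


class _CoxProblem:
    """Sorted arrays and tie-group bookkeeping for one (time, event, X)."""

    def __init__(self, time, event, X, offset=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if time.shape[0] != X.shape[0] or event.shape[0] != X.shape[0]:
            raise ValueError("time, event and X must have matching length")
        if not event.any():
            raise ValueError("no events in the sample; Cox model undefined")
        order = np.argsort(time, kind="stable")
        self.t = time[order]
        self.d = event[order]
        self.X = X[order]
        self.offset = (np.zeros_like(self.t) if offset is None
                       else np.asarray(offset, dtype=float)[order])
        self.order = order
        self.n, self.p = self.X.shape
        self.n_events = int(event.sum())

        ev_idx = np.flatnonzero(self.d)
        ev_t = self.t[ev_idx]
        new_group = np.r_[True, np.diff(ev_t) != 0]
        self.group_start = ev_idx[new_group]            # index into sorted arrays
        self.group_sizes = np.diff(np.r_[np.flatnonzero(new_group), ev_t.size])
        self.group_times = ev_t[new_group]
        # risk-set entry index per group (first row with t >= group time)
        self.risk_start = np.searchsorted(self.t, self.group_times, side="left")
        self.ev_idx = ev_idx
        self.ev_group_starts = np.flatnonzero(new_group)
        # within-group rank l = 0..d-1 for each event occurrence
        offsets = np.repeat(np.r_[0, np.cumsum(self.group_sizes)[:-1]],
                            self.group_sizes)
        self.l = np.arange(ev_idx.size) - offsets
        self.frac_efron = self.l / np.repeat(self.group_sizes, self.group_sizes)
        self.rep = np.repeat(np.arange(self.group_sizes.size), self.group_sizes)

    def quantities(self, beta, ties="efron", need_hessian=True,
                   need_grad=True):
        """Partial log-likelihood, score and observed information.

        Risk-set sums are reverse cumulative sums; all tie-group (Efron)
        contractions are expressed through per-group scalar weights so no
        (n, p, p) intermediate is ever allocated.
        """
        eta = self.X @ beta + self.offset
        shift = eta.max()
        w = np.exp(eta - shift)
        ev = self.ev_idx
        A0 = _revcumsum(w)
        S0g = A0[self.risk_start]
        s0g = np.add.reduceat(w[ev], self.ev_group_starts)
        frac = self.frac_efron if ties == "efron" else np.zeros_like(self.frac_efron)
        rep = self.rep
        D = S0g[rep] - frac * s0g[rep]
        loglik = float(eta[ev].sum() - ev.size * shift - np.log(D).sum())
        if not need_grad:
            return loglik, None, None

        wX = w[:, None] * self.X
        A1 = _revcumsum(wX)
        S1g = A1[self.risk_start]
        s1g = np.add.reduceat(wX[ev], self.ev_group_starts)
        invD = 1.0 / D
        gs = self.ev_group_starts
        a = np.add.reduceat(invD, gs)                       # sum_l 1/D
        b = np.add.reduceat(frac * invD, gs)                # sum_l frac/D
        grad = self.X[ev].sum(axis=0) \
            - (S1g * a[:, None] - s1g * b[:, None]).sum(axis=0)
        if not need_hessian:
            return loglik, grad, None

        invD2 = invD * invD
        c = np.add.reduceat(invD2, gs)
        d = np.add.reduceat(frac * invD2, gs)
        e2 = np.add.reduceat(frac * frac * invD2, gs)
        # sum_g a_g S2_g via cumulative per-row weights C_n
        u = np.zeros(self.n)
        np.add.at(u, self.risk_start, a)
        C = np.cumsum(u)
        term1 = np.einsum("n,np,nq->pq", w * C, self.X, self.X)
        term2 = np.einsum("e,ep,eq->pq", b[rep] * w[ev],
                          self.X[ev], self.X[ev])
        term3 = (np.einsum("g,gp,gq->pq", c, S1g, S1g)
                 - np.einsum("g,gp,gq->pq", d, S1g, s1g)
                 - np.einsum("g,gp,gq->pq", d, s1g, S1g)
                 + np.einsum("g,gp,gq->pq", e2, s1g, s1g))
        info = term1 - term2 - term3
        return loglik, grad, info


@dataclasses.dataclass
class CoxFit:
    """Maximum partial-likelihood fit with Wald inference."""
    names: list
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool
    ties: str
    n: int
    n_events: int
    flags: list
    info: np.ndarray = dataclasses.field(repr=False, default=None)

    def __getitem__(self, name: str) -> dict:
        j = self.names.index(name)
        return {"beta": float(self.beta[j]), "se": float(self.se[j]),
                "hr": float(self.hr[j]), "ci_low": float(self.ci_low[j]),
                "ci_high": float(self.ci_high[j]), "p": float(self.p[j])}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta, "se": self.se, "hr": self.hr,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        }, index=pd.Index(self.names, name="covariate"))

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": {n: self[n] for n in self.names},
            "loglik": self.loglik, "loglik_null": self.loglik_null,
            "iterations": self.iterations, "converged": self.converged,
            "ties": self.ties, "n": self.n, "n_events": self.n_events,
            "flags": self.flags,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        raise RankDeficiencyError("empty design matrix")
    _, R = np.linalg.qr(X - X.mean(axis=0))
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[j] for j in range(len(names)) if diag[j] <= tol]
    if bad:
        raise RankDeficiencyError(
            f"design matrix rank-deficient; suspect column(s): {', '.join(bad)}")


def fit_cox(time, event, X, names: Sequence[str] | None = None,
            ties: str = "efron", tol: float = 1e-8, max_iter: int = 50,
            beta0=None, offset=None, check_rank: bool = True) -> CoxFit:
    """Cox proportional-hazards regression by Newton-Raphson.

    Step-halving guarantees a monotone likelihood path; convergence is
    declared at ``max|score| < tol``. Monotone-likelihood (perfect
    separation) is flagged, never silently reported as converged.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    prob = _CoxProblem(time, event, X, offset=offset)
    if check_rank:
        _check_rank(prob.X, list(names) if names is not None
                    else [f"x{j}" for j in range(prob.p)])
    names = list(names) if names is not None else [f"x{j}" for j in range(prob.p)]

    beta = np.zeros(prob.p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll_null, _, _ = prob.quantities(np.zeros(prob.p), ties=ties, need_hessian=False)
    ll, grad, info = prob.quantities(beta, ties=ties)
    grad_scale = max(1.0, float(np.max(np.abs(grad))))
    flags: list[str] = []
    converged = bool(np.max(np.abs(grad)) < tol)
    it = 0
    while it < max_iter and not converged:
        it += 1
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            info = info + 1e-8 * np.eye(prob.p)
            step = np.linalg.solve(info, grad)
            flags.append("singular information matrix; ridge step taken")
        new_beta = beta + step
        new_ll, _, _ = prob.quantities(new_beta, ties=ties, need_grad=False)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, _, _ = prob.quantities(new_beta, ties=ties, need_grad=False)
            halvings += 1
        improvement = new_ll - ll
        beta = new_beta
        ll, grad, info = prob.quantities(beta, ties=ties)
        max_grad = float(np.max(np.abs(grad)))
        if max_grad < tol:
            converged = True
        elif improvement < 1e-10 * (1.0 + abs(ll)) and \
                max_grad < 1e-6 * grad_scale:
            # float64 accumulation floor on large risk-set sums
            converged = True
            flags.append("converged at numerical gradient floor "
                         f"(max|score|={max_grad:.2e})")
    if not converged:
        flags.append("did not converge within iteration budget")
    runaway = [names[j] for j in range(prob.p) if abs(beta[j]) > 10]
    if runaway:
        converged = False
        flags.append("possible monotone likelihood (perfect separation) in: "
                     + ", ".join(runaway))

    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = 1.959963984540054
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        ci_low = np.exp(beta - z * se)
        ci_high = np.exp(beta + z * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, beta / se, np.inf)
    p = 2 * stats.norm.sf(np.abs(wald))
    return CoxFit(names=names, beta=beta, se=se, hr=hr, ci_low=ci_low,
                  ci_high=ci_high, p=p, loglik=ll, loglik_null=ll_null,
                  iterations=it, converged=converged, ties=ties,
                  n=prob.n, n_events=prob.n_events, flags=flags, info=info)


def fit_cox_frame(cohort: pd.DataFrame, spec: ModelSpec = DEFAULT_MODEL_SPEC,
                  drop_constant: bool = False, **kwargs) -> CoxFit:
    """Fit a Cox model from a validated cohort frame and a model spec."""
    X, names = build_design(cohort, spec, drop_constant=drop_constant)
    return fit_cox(cohort["time_days"].to_numpy(),
                   cohort["event"].to_numpy(bool), X, names=names, **kwargs)


def breslow_cumulative_hazard(time, event, eta):
    """Breslow baseline cumulative hazard evaluated at each subject's time.

    Returns ``(H0_at_subject_times, event_times, increments)``. Used by the
    shared-frailty EM, which needs per-cluster cumulative hazards.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    shift = eta.max()
    w = np.exp(eta[order] - shift)
    A0 = _revcumsum(w)
    ev_idx = np.flatnonzero(d)
    ev_t = t[ev_idx]
    new_group = np.r_[True, np.diff(ev_t) != 0]
    group_times = ev_t[new_group]
    group_sizes = np.diff(np.r_[np.flatnonzero(new_group), ev_t.size])
    risk_start = np.searchsorted(t, group_times, side="left")
    increments = group_sizes / (A0[risk_start] * np.exp(shift))
    H0_steps = np.cumsum(increments)
    idx = np.searchsorted(group_times, time, side="right") - 1
    H0_at = np.where(idx >= 0, H0_steps[np.clip(idx, 0, None)], 0.0)
    return H0_at, group_times, increments


# ---------------------------------------------------------------------------
# Scaled Schoenfeld residuals and proportional-hazards test

@dataclasses.dataclass
class SchoenfeldResiduals:
    """Per-event scaled residuals and a correlation-with-time score test.

    The test regresses the scaled residuals on event time (identity
    transform); a covariate with p >= 0.05 is declared not to violate the
    proportional-hazards assumption. With fewer than 3 events the test is
    undefined and flagged.
    """
    event_times: np.ndarray
    residuals: np.ndarray           # events x covariates, unscaled
    scaled: np.ndarray              # events x covariates
    names: list
    statistic: np.ndarray
    p: np.ndarray
    defined: bool

    def violated(self, alpha: float = 0.05) -> dict:
        if not self.defined:
            return {n: None for n in self.names}
        return {n: bool(self.p[j] < alpha) for j, n in enumerate(self.names)}


def schoenfeld_residuals(fit: CoxFit, time, event, X,
                         offset=None) -> SchoenfeldResiduals:
    if not fit.converged:
        raise ValueError("Schoenfeld residuals require a converged fit")
    prob = _CoxProblem(time, event, X, offset=offset)
    eta = prob.X @ fit.beta + prob.offset
    shift = eta.max()
    w = np.exp(eta - shift)
    wX = w[:, None] * prob.X
    A0, A1 = _revcumsum(w), _revcumsum(wX)
    ev = prob.ev_idx
    S0g, S1g = A0[prob.risk_start], A1[prob.risk_start]
    s0g = np.add.reduceat(w[ev], prob.ev_group_starts)
    s1g = np.add.reduceat(wX[ev], prob.ev_group_starts)
    frac = prob.frac_efron if fit.ties == "efron" else np.zeros_like(prob.frac_efron)
    rep = np.repeat(np.arange(prob.group_sizes.size), prob.group_sizes)
    D = S0g[rep] - frac * s0g[rep]
    xbar = (S1g[rep] - frac[:, None] * s1g[rep]) / D[:, None]
    resid = prob.X[ev] - xbar
    d_total = ev.size

    vinv = np.linalg.inv(fit.info)
    scaled = d_total * resid @ vinv + fit.beta

    ev_times = prob.t[ev]
    if d_total < 3:
        nan = np.full(prob.p, np.nan)
        return SchoenfeldResiduals(ev_times, resid, scaled, fit.names,
                                   nan, nan, defined=False)
    g = ev_times - ev_times.mean()
    u = g @ resid                                  # p-vector
    z = d_total * (vinv @ u)
    var = d_total * np.diag(vinv) * (g @ g)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, z ** 2 / var, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return SchoenfeldResiduals(ev_times, resid, scaled, fit.names,
                               chi2, p, defined=True)
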