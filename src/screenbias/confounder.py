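"""External-adjustment sensitivity analysis for an unmeasured confounder.

Quantifies how an observed Cox hazard ratio would shift if a binary
confounder with hazard ratio ``gamma`` were present at prevalence
``prev_exposed`` in the exposed arm (e.g. screened, or XF residents) and
``prev_unexposed`` in the comparator arm. The classical array-approach
adjustment is multiplicative:

    HR_adj = HR_obs x [p0 g + (1 - p0)] / [p1 g + (1 - p1)]

with ``p1 = prev_exposed``, ``p0 = prev_unexposed``; confidence limits are
scaled by the same factor. Prevalences are mandatory explicit inputs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import pandas as pd

__all__ = ["ConfounderScenario", "AdjustedHR", "adjust_hr_for_confounder",
           "sensitivity_grid"]


@dataclasses.dataclass(frozen=True)
class ConfounderScenario:
    gamma: float                # hazard ratio of the unmeasured confounder
    prev_exposed: float         # confounder prevalence in the exposed arm
    prev_unexposed: float
    observed_hr: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for name in ("prev_exposed", "prev_unexposed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.observed_hr <= 0:
            raise ValueError("observed_hr must be positive")


@dataclasses.dataclass(frozen=True)
class AdjustedHR:
    hr: float
    ci_low: float | None
    ci_high: float | None
    factor: float

    @property
    def ci_crosses_one(self) -> bool | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return self.ci_low <= 1.0 <= self.ci_high


def adjust_hr_for_confounder(scenario: ConfounderScenario) -> AdjustedHR:
    """Externally adjust an observed HR for the specified confounder."""
    g = scenario.gamma
    p1, p0 = scenario.prev_exposed, scenario.prev_unexposed
    factor = (p0 * g + (1 - p0)) / (p1 * g + (1 - p1))
    return AdjustedHR(
        hr=scenario.observed_hr * factor,
        ci_low=None if scenario.ci_low is None else scenario.ci_low * factor,
        ci_high=None if scenario.ci_high is None else scenario.ci_high * factor,
        factor=factor)


def sensitivity_grid(observed: dict, gammas: Iterable[float],
                     prev_exposed: Iterable[float],
                     prev_unexposed: Iterable[float]) -> pd.DataFrame:
    """Cross-product sensitivity table for one or more observed HRs.

    ``observed`` maps an effect label (e.g. ``"screened"``) to a dict with
    ``hr``, ``ci_low``, ``ci_high``. Cells whose adjusted CI crosses 1 are
    flagged in the ``crosses_one`` column.
    """
    rows = []
    for label, est in observed.items():
        for g in gammas:
            for p1 in prev_exposed:
                for p0 in prev_unexposed:
                    adj = adjust_hr_for_confounder(ConfounderScenario(
                        gamma=g, prev_exposed=p1, prev_unexposed=p0,
                        observed_hr=est["hr"], ci_low=est.get("ci_low"),
                        ci_high=est.get("ci_high")))
                    rows.append({
                        "effect": label, "gamma": g,
                        "prev_exposed": p1, "prev_unexposed": p0,
                        "observed_hr": est["hr"], "adjusted_hr": adj.hr,
                        "adjusted_ci_low": adj.ci_low,
                        "adjusted_ci_high": adj.ci_high,
                        "crosses_one": adj.ci_crosses_one,
                    })
    return pd.DataFrame(rows)
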