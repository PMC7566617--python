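"""Patient-level cohort data model, CSV I/O and stratified summaries.

The cohort is carried in memory as a validated :class:`pandas.DataFrame`
(one row per patient, columns as in :class:`PatientRecord`); the dataclass
form is available for row-level work. Summaries stratify by region of
residence x diagnosed-by-screening and expose the derived quantities used
throughout the analysis (sex ratios, screened fractions, per-stage screened
shares).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("nonXF", "XF")
SEXES = ("female", "male")
ETHNICITIES = ("Han", "nonHan")
STAGES = ("I", "II", "III", "IV")
HISTOLOGIES = ("adenocarcinoma", "squamous", "small_cell", "other")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

STRATA = [(r, s) for r in REGIONS for s in (False, True)]

_BOOL_COLUMNS = ("screened", "cci_gt3", "kps_gt70", "smoker",
                 "surgery", "chemo", "radio", "targeted", "event")
_ENUM_COLUMNS = {
    "region": REGIONS,
    "sex": SEXES,
    "ethnicity": ETHNICITIES,
    "stage": STAGES,
    "histology": HISTOLOGIES,
    "bmi_category": BMI_CATEGORIES,
}
#: Categorical variables tabulated in cohort summaries.
SUMMARY_VARIABLES = ("sex", "ethnicity", "stage", "histology", "bmi_category",
                     "cci_gt3", "kps_gt70", "smoker", "surgery", "chemo",
                     "radio", "targeted")

COLUMNS = ("id", "region", "screened", "age_years", "sex", "ethnicity",
           "stage", "histology", "bmi_category", "cci_gt3", "kps_gt70",
           "smoker", "surgery", "chemo", "radio", "targeted",
           "time_days", "event")

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class CohortSchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class CohortValidationError(ValueError):
    """A cell failed validation; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


@dataclasses.dataclass
class PatientRecord:
    """One subject of the cohort (observable fields only)."""

    id: str
    region: str                 # "XF" | "nonXF"
    screened: bool              # diagnosed by screening
    age_years: float
    sex: str                    # "female" | "male"
    ethnicity: str              # "Han" | "nonHan"
    stage: str                  # "I" .. "IV"
    histology: str
    bmi_category: str
    cci_gt3: bool               # age-unadjusted Charlson index > 3
    kps_gt70: bool              # Karnofsky performance score > 70
    smoker: bool
    surgery: bool
    chemo: bool
    radio: bool
    targeted: bool
    time_days: float            # diagnosis to death / last follow-up
    event: bool                 # death observed

    def __post_init__(self):
        for col, levels in _ENUM_COLUMNS.items():
            value = getattr(self, col)
            if value not in levels:
                raise CohortValidationError(
                    f"invalid {col} {value!r}; expected one of {levels}")
        if not self.time_days > 0:
            raise CohortValidationError(
                f"time_days must be positive, got {self.time_days}")
        if not self.age_years > 0:
            raise CohortValidationError(
                f"age_years must be positive, got {self.age_years}")


def bmi_category_from_bmi(bmi: float) -> str:
    """Asian-Pacific BMI classification."""
    if bmi < 18.5:
        return "underweight"
    if bmi < 23:
        return "normal"
    if bmi < 25:
        return "overweight"
    return "obese"


def _parse_bool(value, col: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise CohortValidationError(f"unparsable boolean {value!r} in column {col!r}", row)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a raw cohort table.

    Raw ``bmi`` / ``cci`` / ``kps`` columns are discretized only when the
    corresponding categorical column is absent; explicit categorical columns
    take precedence. Unknown columns are dropped with a warning.
    """
    df = df.copy()
    if "bmi_category" not in df.columns and "bmi" in df.columns:
        df["bmi_category"] = df["bmi"].astype(float).map(bmi_category_from_bmi)
    if "cci_gt3" not in df.columns and "cci" in df.columns:
        df["cci_gt3"] = df["cci"].astype(float) > 3
    if "kps_gt70" not in df.columns and "kps" in df.columns:
        df["kps_gt70"] = df["kps"].astype(float) > 70

    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s): %s", ", ".join(extra))
        df = df.drop(columns=extra)

    out = pd.DataFrame(index=df.index)
    out["id"] = df["id"].astype(str)
    for col in ("region", "sex", "ethnicity", "stage", "histology", "bmi_category"):
        values = df[col].astype(str).str.strip()
        levels = _ENUM_COLUMNS[col]
        bad = ~values.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"invalid {col} {values.iloc[row]!r}; expected one of {levels}", row)
        out[col] = values
    for col in _BOOL_COLUMNS:
        out[col] = [_parse_bool(v, col, i) for i, v in enumerate(df[col])]
    for col in ("age_years", "time_days"):
        try:
            out[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"unparsable numeric column {col!r}: {exc}")
        nonpos = ~(out[col] > 0)
        if nonpos.any():
            row = int(np.flatnonzero(nonpos.to_numpy())[0])
            raise CohortValidationError(f"non-positive {col}", row)
    return out[list(COLUMNS)].reset_index(drop=True)


def read_cohort(path, delimiter: str = ",",
                column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV (header row mandatory).

    ``column_map`` renames input columns to the canonical schema, e.g.
    ``{"fu_days": "time_days"}``.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a validated cohort back to CSV (lossless round-trip)."""
    out = cohort.copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(bool).map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def to_records(cohort: pd.DataFrame) -> list[PatientRecord]:
    return [PatientRecord(**row) for row in cohort.to_dict("records")]


def from_records(records: list[PatientRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("empty record collection")
    return validate_cohort(pd.DataFrame([dataclasses.asdict(r) for r in records]))


# ---------------------------------------------------------------------------
# Stratified summaries


@dataclasses.dataclass
class CohortSummary:
    """Region x screening stratified counts and derived ratios.

    ``counts[var][stratum][level]`` are cell counts; strata are
    ``(region, screened)`` pairs. Sex ratios are male/female counts and are
    flagged undefined (NaN) for strata without females.
    """

    stratum_n: dict
    counts: dict
    proportions: dict
    sex_ratio: dict
    sex_ratio_defined: dict
    screened_fraction_by_region: dict
    screened_fraction_overall: float
    screened_fraction_by_stage: dict
    stage1_screened_region_share: dict

    @classmethod
    def from_counts(cls, stratum_counts: Mapping[str, Mapping],
                    stratum_n: Mapping | None = None) -> "CohortSummary":
        """Build a summary directly from stratified count tables.

        Used both by :func:`summarize_cohort` and to evaluate derived
        quantities on the published cohort composition.
        """
        counts = {var: {s: dict(cells) for s, cells in by_stratum.items()}
                  for var, by_stratum in stratum_counts.items()}
        if stratum_n is None:
            first = next(iter(counts.values()))
            stratum_n = {s: sum(cells.values()) for s, cells in first.items()}
        stratum_n = dict(stratum_n)

        proportions = {
            var: {s: {lev: c / stratum_n[s] if stratum_n[s] else np.nan
                      for lev, c in cells.items()}
                  for s, cells in by_stratum.items()}
            for var, by_stratum in counts.items()}

        sex_ratio, sex_defined = {}, {}
        for s, cells in counts.get("sex", {}).items():
            female = cells.get("female", 0)
            male = cells.get("male", 0)
            if female == 0:
                sex_ratio[s], sex_defined[s] = np.nan, False
            else:
                sex_ratio[s], sex_defined[s] = male / female, True

        screened_by_region = {}
        for region in {s[0] for s in stratum_n}:
            tot = sum(n for (r, _), n in stratum_n.items() if r == region)
            scr = sum(n for (r, sc), n in stratum_n.items() if r == region and sc)
            screened_by_region[region] = scr / tot if tot else np.nan
        total = sum(stratum_n.values())
        screened_overall = (sum(n for (_, sc), n in stratum_n.items() if sc) / total
                            if total else np.nan)

        screened_by_stage, stage1_share = {}, {}
        stage_counts = counts.get("stage", {})
        if stage_counts:
            for stage in STAGES:
                tot = sum(cells.get(stage, 0) for cells in stage_counts.values())
                scr = sum(cells.get(stage, 0)
                          for (_, sc), cells in stage_counts.items() if sc)
                screened_by_stage[stage] = scr / tot if tot else np.nan
            scr1 = {r: cells.get("I", 0)
                    for (r, sc), cells in stage_counts.items() if sc}
            tot1 = sum(scr1.values())
            stage1_share = {r: c / tot1 if tot1 else np.nan for r, c in scr1.items()}

        return cls(stratum_n, counts, proportions, sex_ratio, sex_defined,
                   screened_by_region, screened_overall, screened_by_stage,
                   stage1_share)

    def to_dict(self) -> dict:
        def keyed(d):
            return {f"{r}|{'screened' if s else 'unscreened'}": v
                    for (r, s), v in d.items()}
        return {
            "stratum_n": keyed(self.stratum_n),
            "counts": {v: keyed(c) for v, c in self.counts.items()},
            "proportions": {v: keyed(c) for v, c in self.proportions.items()},
            "sex_ratio": keyed(self.sex_ratio),
            "sex_ratio_defined": keyed(self.sex_ratio_defined),
            "screened_fraction_by_region": self.screened_fraction_by_region,
            "screened_fraction_overall": self.screened_fraction_overall,
            "screened_fraction_by_stage": self.screened_fraction_by_stage,
            "stage1_screened_region_share": self.stage1_screened_region_share,
        }

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=default,
                          allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        """Long-format count/proportion table (one row per variable cell)."""
        rows = []
        for var, by_stratum in self.counts.items():
            for (region, screened), cells in by_stratum.items():
                for level, count in cells.items():
                    rows.append({
                        "variable": var, "level": level, "region": region,
                        "screened": screened, "count": count,
                        "proportion": self.proportions[var][(region, screened)][level],
                    })
        return pd.DataFrame(rows)


def summarize_cohort(cohort: pd.DataFrame) -> CohortSummary:
    """Stratified Table-1-style summary of a validated cohort."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    stratum_n = {}
    stratum_counts: dict = {var: {} for var in SUMMARY_VARIABLES}
    for region, screened in STRATA:
        mask = (cohort["region"] == region) & (cohort["screened"] == screened)
        sub = cohort[mask]
        stratum_n[(region, screened)] = int(mask.sum())
        for var in SUMMARY_VARIABLES:
            if var in _ENUM_COLUMNS:
                levels = _ENUM_COLUMNS[var]
                vc = sub[var].value_counts()
                cells = {lev: int(vc.get(lev, 0)) for lev in levels}
            else:  # boolean variable
                cells = {"no": int((~sub[var].astype(bool)).sum()),
                         "yes": int(sub[var].astype(bool).sum())}
            stratum_counts[var][(region, screened)] = cells
    return CohortSummary.from_counts(stratum_counts, stratum_n)


def published_summary() -> CohortSummary:
    """Summary built from the published cohort composition (see study.py)."""
    from . import study
    strata = {(r, bool(s)): n for (r, s), n in study.STRATUM_N.items()}
    counts = {}
    for var, by_stratum in study.STRATUM_COUNTS.items():
        counts[var] = {(r, bool(s)): dict(cells)
                       for (r, s), cells in by_stratum.items()}
    return CohortSummary.from_counts(counts, strata)
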