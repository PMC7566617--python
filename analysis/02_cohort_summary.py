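"""Stratified cohort description and the published derived quantities.

Summarises the simulated cohort by region x detection mode, and recomputes
from the study's published stratified counts the quantities the analysis
anchors on: sex ratios 2.62 / 1.37, screened fractions 17.6% / 5.3% / 7.8%,
and the 46.6% XF share among screened stage-I cases.
"""

import json
from pathlib import Path

from screenbias.cohort import published_summary, read_cohort, summarize_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    cohort = read_cohort(OUT / "cohort.csv")
    summary = summarize_cohort(cohort)
    summary.to_json(OUT / "summary.json")
    summary.to_frame().to_csv(OUT / "summary.csv", index=False)

    pub = published_summary()
    derived = {
        "sex_ratio_nonXF_unscreened": round(pub.sex_ratio[("nonXF", False)], 2),
        "sex_ratio_XF_screened": round(pub.sex_ratio[("XF", True)], 2),
        "screened_pct_XF": round(100 * pub.screened_fraction_by_region["XF"], 1),
        "screened_pct_nonXF": round(100 * pub.screened_fraction_by_region["nonXF"], 1),
        "screened_pct_overall": round(100 * pub.screened_fraction_overall, 1),
        "stage1_screened_pct": round(100 * pub.screened_fraction_by_stage["I"], 1),
        "stage1_screened_XF_share_pct": round(
            100 * pub.stage1_screened_region_share["XF"], 1),
    }
    (OUT / "published_quantities.json").write_text(
        json.dumps(derived, indent=2, sort_keys=True))

    print("published-count derived quantities:")
    for key, value in derived.items():
        print(f"  {key}: {value}")
    print("\nsimulated cohort, screened fraction by region:",
          {k: round(v, 3) for k, v in summary.screened_fraction_by_region.items()})
    print(f"wrote {OUT/'summary.json'}, summary.csv, published_quantities.json")


if __name__ == "__main__":
    main()
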