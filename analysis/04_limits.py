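"""Confidence, tolerance and action limits — the published table rebuilt.

Two derivations side by side:

1. **Closed form from the published statistics** — the printed site means/SDs
   fed through the confidence-limit and action-limit formulas (the tolerance
   limit needs the unpublished per-plan sequences, so it has no closed-form
   column here).
2. **Recovered from generated cohorts** — the full pipeline on synthetic
   series (n = 10/site), including I-chart tolerance limits, which exist for
   a concrete sequence.

Writes results/limits_closed_form.csv (and the pipeline limits are under
results/clinical/limits.csv from script 03).
"""

import sys
from pathlib import Path

import pandas as pd

from protonqa import datasets
from protonqa.spc import RateSummary, action_limits, confidence_limit

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = datasets.clinical_summary()
    rows = []
    for _, row in summary[summary.criteria != "3%/2mm"].iterrows():
        stats = RateSummary(row["mean"], row["sd"], datasets.PLANS_PER_SITE)
        _, _, lower = action_limits(stats)
        rows.append(
            {
                "site": row["site"],
                "criteria": row["criteria"],
                "confidence_limit": round(confidence_limit(stats), 1),
                "action_limit": round(lower, 1),
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "limits_closed_form.csv", index=False)
    print("closed-form limits from the published site statistics:")
    print(table.to_string(index=False))
    print("\npooled rows: 3%/3mm CL = "
          f"{table[(table.site == 'All regions') & (table.criteria == '3%/3mm')]['confidence_limit'].iloc[0]}"
          ", 5%/3mm CL = "
          f"{table[(table.site == 'All regions') & (table.criteria == '5%/3mm')]['confidence_limit'].iloc[0]}")
    print(f"\n-> {OUT / 'limits_closed_form.csv'}")


if __name__ == "__main__":
    sys.exit(main())
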