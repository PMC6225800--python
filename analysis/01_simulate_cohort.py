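#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Two cohorts are produced:

* a tabular cohort of 2756 knees (grades, pain reports, demographics) at
  the study's sample size, used by the single-feature screen and the
  manual-grade comparisons;
* a rendered PA cohort of 260 knees (images + ground-truth landmarks),
  sized so the landmark/appearance pipeline trains and evaluates in desk
  time, used by the automated-feature analyses.

Images and per-knee files go to scratch/; a small summary table goes to
results/.
"""

from pathlib import Path

import pandas as pd

from kneestudy.cohort import CohortConfig, generate_cohort, generate_cohort_table
from kneestudy.outcomes import derive_labels

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort_pa"
RESULTS = ROOT / "results"

TABULAR_N = 2756
RENDERED_N = 260
SEED = 20260923


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    tab = generate_cohort_table(CohortConfig(n_subjects=TABULAR_N, seed=SEED))
    tab.to_csv(SCRATCH.parent / "cohort_tabular.csv", float_format="%.6f")

    knees, manifest = generate_cohort(
        CohortConfig(n_subjects=RENDERED_N, seed=SEED + 1), out_dir=SCRATCH
    )

    rows = []
    for name, df in [("tabular", tab), ("rendered", manifest)]:
        cons = derive_labels(df, "CONSISTENT")
        rows.append(
            {
                "cohort": name,
                "n": len(df),
                "clinic_pain_prevalence": df["clinic"].mean(),
                "consistent_pain_n": int(cons.notna().sum()),
                "consistent_excluded_n": int(cons.isna().sum()),
                "widespread_n": int(df["widespread"].sum()),
                "mean_age": df["age"].mean(),
                "mean_bmi": df["bmi"].mean(),
                "prop_female": df["sex"].mean(),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False, float_format="%.4f")
    print(summary.to_string(index=False))
    print(f"\nrendered cohort written to {SCRATCH}")


if __name__ == "__main__":
    main()
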