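#!/usr/bin/env python
"""Compare feature sets across all four pain outcomes.

Two grids:

* on the tabular cohort (n = 2756): manual grades, manual + sex/BMI, and
  the widespread-pain exclusion, for each outcome — the analogue of the
  manual rows of the feature-set comparison;
* on the rendered cohort (n = 260): adds the automated feature sets
  (best-of nested selection among shape / texture / combined) and the
  manual+automated concatenation.

Each non-referent row carries a DeLong p-value against the manual-grades
referent of its outcome.
"""

from pathlib import Path

import pandas as pd

from kneestudy.evaluate import CVConfig, table_runner
from kneestudy.outcomes import FeatureSet, FeatureSetSpec, OutcomeMode

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

SEED = 20260923


def main() -> None:
    cfg = CVConfig(seed=SEED)
    tabular = pd.read_csv(ROOT / "scratch" / "cohort_tabular.csv", index_col=0)
    specs = []
    for outcome in OutcomeMode:
        specs += [
            (outcome, FeatureSetSpec(FeatureSet.MANUAL), False),
            (outcome, FeatureSetSpec(FeatureSet.MANUAL_DEMO), False),
            (outcome, FeatureSetSpec(FeatureSet.MANUAL_DEMO), True),
        ]
    t_tab = table_runner(tabular, specs, cfg)
    t_tab.to_csv(
        RESULTS / "feature_set_comparison_tabular.csv",
        index=False,
        float_format="%.4f",
    )
    print("tabular cohort (n=2756):")
    print(t_tab.to_string(index=False))

    rendered = pd.read_csv(ROOT / "scratch" / "cohort_pa" / "cohort.csv", index_col=0)
    automated = pd.read_csv(ROOT / "scratch" / "features_auto.csv", index_col=0)
    specs_img = []
    for outcome in OutcomeMode:
        specs_img += [
            (outcome, FeatureSetSpec(FeatureSet.MANUAL), False),
            (outcome, FeatureSetSpec(FeatureSet.BEST_AUTO), False),
            (outcome, FeatureSetSpec(FeatureSet.MANUAL_PLUS_AUTO), False),
        ]
    t_img = table_runner(rendered, specs_img, cfg, automated=automated)
    t_img.to_csv(
        RESULTS / "feature_set_comparison_imaged.csv",
        index=False,
        float_format="%.4f",
    )
    print("\nrendered cohort (n=260, automated features):")
    print(t_img.to_string(index=False))


if __name__ == "__main__":
    main()
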