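"""Pain outcomes, widespread-pain exclusion and feature-matrix assembly.

Frequent knee pain is reported three times around the baseline visit — a
telephone screen (``tscreen``), a self-assessed questionnaire (``saq``) and
a clinic interview (``clinic``).  Each single instrument defines a binary
outcome; the *consistent pain* outcome keeps only subjects whose three
answers agree (all yes -> positive, all no -> negative, otherwise excluded).
Subjects reporting widespread body pain can optionally be excluded, on the
assumption that their knee pain is not of osteoarthritic origin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grading import GRADE_COLUMNS, feature_by_name

PAIN_REPORT_COLUMNS = ["tscreen", "saq", "clinic"]


@dataclass(frozen=True)
class PainRecord:
    """Three binary pain reports plus the widespread-pain flag."""

    tscreen: int
    saq: int
    clinic: int
    widespread: int

    def __post_init__(self) -> None:
        for name in ("tscreen", "saq", "clinic", "widespread"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")

    @property
    def reports(self) -> tuple[int, int, int]:
        return (self.tscreen, self.saq, self.clinic)


class OutcomeMode(str, enum.Enum):
    TSCREEN = "TSCREEN"
    SAQ = "SAQ"
    CLINIC = "CLINIC"
    CONSISTENT = "CONSISTENT"


class Label(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class PainOutcome:
    mode: OutcomeMode
    label: Label


def derive_outcome(record: PainRecord, mode: OutcomeMode | str) -> PainOutcome:
    """Derive the classification label for one record under an outcome mode.

    Single-instrument modes take that instrument's answer.  CONSISTENT maps
    unanimous yes to POSITIVE, unanimous no to NEGATIVE and any disagreement
    to EXCLUDED.
    """
    mode = OutcomeMode(mode)
    if mode is OutcomeMode.CONSISTENT:
        if record.reports == (1, 1, 1):
            label = Label.POSITIVE
        elif record.reports == (0, 0, 0):
            label = Label.NEGATIVE
        else:
            label = Label.EXCLUDED
    else:
        v = getattr(record, mode.value.lower())
        label = Label.POSITIVE if v == 1 else Label.NEGATIVE
    return PainOutcome(mode=mode, label=label)


def derive_labels(df: pd.DataFrame, mode: OutcomeMode | str) -> pd.Series:
    """Vectorised :func:`derive_outcome` over a cohort table.

    Returns a Series of {0, 1, NaN}; NaN marks EXCLUDED rows.
    """
    mode = OutcomeMode(mode)
    if mode is OutcomeMode.CONSISTENT:
        s = df[PAIN_REPORT_COLUMNS].sum(axis=1)
        out = pd.Series(np.nan, index=df.index)
        out[s == 3] = 1.0
        out[s == 0] = 0.0
        return out
    return df[mode.value.lower()].astype(float)


def filter_widespread(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows flagged with widespread pain; return (kept, n_removed)."""
    mask = df["widespread"].astype(int) == 1
    n_removed = int(mask.sum())
    kept = df.loc[~mask]
    if kept.empty:
        import warnings

        warnings.warn("all rows flagged widespread; nothing kept", stacklevel=2)
    return kept, n_removed


class FeatureSet(str, enum.Enum):
    SINGLE = "SINGLE"
    MANUAL = "MANUAL"
    MANUAL_DEMO = "MANUAL_DEMO"
    AUTO_SHAPE = "AUTO_SHAPE"
    AUTO_TEXTURE = "AUTO_TEXTURE"
    AUTO_COMBINED = "AUTO_COMBINED"
    MANUAL_PLUS_AUTO = "MANUAL_PLUS_AUTO"
    BEST_AUTO = "BEST_AUTO"


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which columns make up the classifier's design matrix.

    ``SINGLE`` requires ``feature`` to name one of the 36 grade features.
    """

    kind: FeatureSet
    feature: str | None = None

    def __post_init__(self) -> None:
        if self.kind is FeatureSet.SINGLE:
            if self.feature is None:
                raise ValueError("SINGLE requires a grade feature name")
            feature_by_name(self.feature)  # raises on unknown names
        elif self.feature is not None:
            raise ValueError(f"{self.kind.value} takes no feature name")


AUTO_PREFIX = {
    FeatureSet.AUTO_SHAPE: "bs_",
    FeatureSet.AUTO_TEXTURE: "bg_",
    FeatureSet.AUTO_COMBINED: "c_",
}


def _auto_columns(features: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in features.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"automated feature table has no '{prefix}*' columns")
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def assemble_features(
    grades: pd.DataFrame,
    spec: FeatureSetSpec,
    automated: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix for one feature-set specification.

    ``grades`` is a cohort table indexed by knee id with the 36 grade
    columns plus ``sex`` and ``bmi``; ``automated`` (indexed by the same
    ids) holds combined-appearance (``c_k``), shape-only (``bs_k``) and
    texture-only (``bg_k``) parameter columns.  Column ordering is
    deterministic: grade columns in reading-sheet order, automated columns
    by parameter index.
    """
    kind = spec.kind
    if kind is FeatureSet.SINGLE:
        cols = [spec.feature]
        return grades[cols].to_numpy(dtype=float), cols
    if kind is FeatureSet.MANUAL:
        return grades[GRADE_COLUMNS].to_numpy(dtype=float), list(GRADE_COLUMNS)
    if kind is FeatureSet.MANUAL_DEMO:
        cols = list(GRADE_COLUMNS) + ["sex", "bmi"]
        return grades[cols].to_numpy(dtype=float), cols

    if automated is None:
        raise ValueError(f"{kind.value} requires the automated feature table")
    missing = grades.index.difference(automated.index)
    if len(missing):
        raise ValueError(
            f"automated features missing for ids: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    automated = automated.loc[grades.index]

    if kind in AUTO_PREFIX:
        cols = _auto_columns(automated, AUTO_PREFIX[kind])
        return automated[cols].to_numpy(dtype=float), cols
    if kind is FeatureSet.MANUAL_PLUS_AUTO:
        auto_cols = _auto_columns(automated, "c_")
        x = np.column_stack(
            [
                grades[GRADE_COLUMNS].to_numpy(dtype=float),
                automated[auto_cols].to_numpy(dtype=float),
            ]
        )
        return x, list(GRADE_COLUMNS) + auto_cols
    raise ValueError(f"cannot assemble a fixed matrix for {kind.value}")
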