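"""Random-forest classification with repeated cross-validated AUC.

The evaluation engine behind both the single-feature screen and the
feature-set comparison: a random forest (40 trees by default) run under
stratified 5-fold cross-validation repeated 5 times.  Each repeat pools
its out-of-fold class-probability scores into one AUC, giving exactly
``n_repeats`` AUCs whose mean and SD are reported.

AUC uses the Mann–Whitney formulation with midrank tie handling,
``P(score+ > score-) + 0.5 P(equal)``.  Two results are compared with a
DeLong covariance-based chi-squared test whose variance adds a
between-repeat component for the refold/retrain noise of cross-validated
scores (paired when both runs used the same rows and fold seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from scipy.stats import f as f_dist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .grading import GRADE_COLUMNS
from .outcomes import (
    FeatureSet,
    FeatureSetSpec,
    OutcomeMode,
    assemble_features,
    derive_labels,
    filter_widespread,
)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC with midrank ties: P(s+ > s-) + 0.5 P(s+ = s-)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present in labels")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# DeLong variance machinery


def _delong_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mid-p placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = float(v10.mean())
    return v10, v01, a


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Paired DeLong test for two score vectors on the same samples.

    Returns (auc_a, auc_b, variance of the AUC difference).
    """
    labels = np.asarray(labels).astype(int)
    va10, va01, auc_a = _delong_placements(np.asarray(scores_a, float), labels)
    vb10, vb01, auc_b = _delong_placements(np.asarray(scores_b, float), labels)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]), ddof=1)
    s01 = np.cov(np.stack([va01, vb01]), ddof=1)
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    return auc_a, auc_b, float(max(var, 0.0))


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of a single AUC."""
    labels = np.asarray(labels).astype(int)
    v10, v01, _ = _delong_placements(np.asarray(scores, float), labels)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


# ---------------------------------------------------------------------------
# repeated cross-validation


@dataclass(frozen=True)
class CVConfig:
    n_trees: int = 40
    n_folds: int = 5
    n_repeats: int = 5
    stratified: bool = True
    #: minimum leaf size as a fraction of the training split; smooths the
    #: class-probability estimates that pooled out-of-fold AUCs rank on
    min_samples_leaf: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if not 0 < self.min_samples_leaf <= 0.5:
            raise ValueError(
                f"min_samples_leaf must be a fraction in (0, 0.5], got {self.min_samples_leaf}"
            )


@dataclass
class ROCResult:
    """Repeated-CV AUC summary plus per-repeat out-of-fold scores."""

    auc_per_repeat: np.ndarray    # (n_repeats,)
    oof_scores: np.ndarray        # (n_repeats, n) out-of-fold probabilities
    labels: np.ndarray            # (n,)
    row_ids: np.ndarray           # (n,) sample identifiers
    config: CVConfig
    extra: dict = field(default_factory=dict)

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc_per_repeat))

    @property
    def auc_sd(self) -> float:
        if len(self.auc_per_repeat) < 2:
            return 0.0
        return float(np.std(self.auc_per_repeat, ddof=1))

    @property
    def mean_oof_scores(self) -> np.ndarray:
        """Per-sample out-of-fold score averaged over repeats."""
        return self.oof_scores.mean(axis=0)


def _check_cv_inputs(x: np.ndarray, y: np.ndarray, config: CVConfig) -> None:
    if len(x) < 2 * config.n_folds:
        raise ValueError(
            f"need at least {2 * config.n_folds} rows for {config.n_folds}-fold CV, got {len(x)}"
        )
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows; stratified "
            f"{config.n_folds}-fold CV needs at least {config.n_folds} per class"
        )


def _splitter(config: CVConfig, repeat: int) -> StratifiedKFold:
    # fresh fold split per repeat, seeded from the config seed + repeat index
    return StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed + repeat
    )


def _rf_state(config: CVConfig, repeat: int, fold: int) -> int:
    return (config.seed + 7919 * (repeat + 1) + 104729 * (fold + 1)) % (2**31)


def run_repeated_cv(
    x: np.ndarray,
    y: np.ndarray,
    config: CVConfig = CVConfig(),
    row_ids: np.ndarray | None = None,
) -> ROCResult:
    """Repeated stratified k-fold CV of a random forest; one pooled
    out-of-fold AUC per repeat."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y).astype(int)
    _check_cv_inputs(x, y, config)
    if row_ids is None:
        row_ids = np.arange(len(y))
    aucs = np.empty(config.n_repeats)
    oof = np.empty((config.n_repeats, len(y)))
    for rep in range(config.n_repeats):
        for fold, (tr, te) in enumerate(_splitter(config, rep).split(x, y)):
            rf = RandomForestClassifier(
                n_estimators=config.n_trees,
                min_samples_leaf=config.min_samples_leaf,
                random_state=_rf_state(config, rep, fold),
                n_jobs=1,
            )
            rf.fit(x[tr], y[tr])
            oof[rep, te] = rf.predict_proba(x[te])[:, list(rf.classes_).index(1)]
        aucs[rep] = auc(oof[rep], y)
    return ROCResult(
        auc_per_repeat=aucs,
        oof_scores=oof,
        labels=y,
        row_ids=np.asarray(row_ids),
        config=config,
    )


def run_repeated_cv_best_auto(
    variants: dict[str, np.ndarray],
    y: np.ndarray,
    config: CVConfig = CVConfig(),
    row_ids: np.ndarray | None = None,
    inner_folds: int = 3,
) -> ROCResult:
    """"Best automated" evaluation with nested variant selection.

    For every outer training split, each automated variant (shape-only,
    texture-only, combined) is scored by a small inner CV on the training
    rows only; the winning variant is refit on the full training split and
    scores the held-out fold.  Selection therefore never sees test rows.
    """
    names = sorted(variants)
    xs = {k: np.asarray(v, dtype=float) for k, v in variants.items()}
    y = np.asarray(y).astype(int)
    first = xs[names[0]]
    _check_cv_inputs(first, y, config)
    if row_ids is None:
        row_ids = np.arange(len(y))
    aucs = np.empty(config.n_repeats)
    oof = np.empty((config.n_repeats, len(y)))
    chosen: list[str] = []
    for rep in range(config.n_repeats):
        for fold, (tr, te) in enumerate(_splitter(config, rep).split(first, y)):
            best_name, best_auc = None, -np.inf
            inner = StratifiedKFold(
                n_splits=inner_folds, shuffle=True,
                random_state=config.seed + 7 * rep + fold,
            )
            for name in names:
                xv = xs[name]
                inner_scores = np.empty(len(tr))
                for itr, ite in inner.split(xv[tr], y[tr]):
                    rf = RandomForestClassifier(
                        n_estimators=config.n_trees,
                        min_samples_leaf=config.min_samples_leaf,
                        random_state=_rf_state(config, rep, fold),
                        n_jobs=1,
                    )
                    rf.fit(xv[tr][itr], y[tr][itr])
                    inner_scores[ite] = rf.predict_proba(xv[tr][ite])[
                        :, list(rf.classes_).index(1)
                    ]
                a = auc(inner_scores, y[tr])
                if a > best_auc:
                    best_name, best_auc = name, a
            chosen.append(best_name)
            rf = RandomForestClassifier(
                n_estimators=config.n_trees,
                min_samples_leaf=config.min_samples_leaf,
                random_state=_rf_state(config, rep, fold),
                n_jobs=1,
            )
            xv = xs[best_name]
            rf.fit(xv[tr], y[tr])
            oof[rep, te] = rf.predict_proba(xv[te])[:, list(rf.classes_).index(1)]
        aucs[rep] = auc(oof[rep], y)
    return ROCResult(
        auc_per_repeat=aucs,
        oof_scores=oof,
        labels=y,
        row_ids=np.asarray(row_ids),
        config=config,
        extra={"chosen_variants": chosen},
    )


# ---------------------------------------------------------------------------
# AUC comparison


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    auc_a: float
    auc_b: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def compare_auc(
    result_a: ROCResult, result_b: ROCResult, paired: bool = True
) -> ComparisonResult:
    """DeLong-based chi-squared test for an AUC difference between two
    repeated-CV runs.

    The AUC difference is the mean of the per-repeat differences.  Its
    variance has two parts: the DeLong (co)variance of the repeat-averaged
    out-of-fold score vectors — paired (covariance subtracted) when both
    runs share samples and fold structure, unpaired (variances added)
    otherwise — plus the between-repeat variance of the difference divided
    by the repeat count, which captures the refold/retrain noise that the
    DeLong term, treating scores as fixed, cannot see.  The squared
    standardised difference is referred to chi-squared(1).
    """
    sa = result_a.mean_oof_scores
    sb = result_b.mean_oof_scores
    n_rep = result_a.oof_scores.shape[0]
    if paired:
        if len(result_a.row_ids) != len(result_b.row_ids) or np.any(
            result_a.row_ids != result_b.row_ids
        ):
            raise ValueError("paired comparison requires identical row ids")
        if result_a.config.seed != result_b.config.seed or (
            result_a.config.n_folds != result_b.config.n_folds
        ):
            raise ValueError(
                "paired comparison requires the same fold structure "
                "(seed and n_folds) in both results"
            )
        if np.any(result_a.labels != result_b.labels):
            raise ValueError("paired comparison requires identical labels")
        auc_a, auc_b, var_scores = delong_paired_test(sa, sb, result_a.labels)
        per_rep_diff = np.array(
            [
                auc(result_a.oof_scores[r], result_a.labels)
                - auc(result_b.oof_scores[r], result_b.labels)
                for r in range(n_rep)
            ]
        )
        method = "paired DeLong + between-repeat variance (Satterthwaite F)"
    else:
        auc_a = auc(sa, result_a.labels)
        auc_b = auc(sb, result_b.labels)
        var_scores = delong_variance(sa, result_a.labels) + delong_variance(
            sb, result_b.labels
        )
        n_rep_b = result_b.oof_scores.shape[0]
        a_r = np.array(
            [auc(result_a.oof_scores[r], result_a.labels) for r in range(n_rep)]
        )
        b_r = np.array(
            [auc(result_b.oof_scores[r], result_b.labels) for r in range(n_rep_b)]
        )
        per_rep_diff = a_r[: min(n_rep, n_rep_b)] - b_r[: min(n_rep, n_rep_b)]
        method = "unpaired DeLong + between-repeat variance (Satterthwaite F)"
    diff = float(per_rep_diff.mean())
    n_diff = len(per_rep_diff)
    var_rep = (
        float(per_rep_diff.var(ddof=1)) / n_diff if n_diff > 1 else 0.0
    )
    var = var_scores + var_rep
    if var < 1e-16:
        stat = 0.0 if abs(diff) < 1e-12 else np.inf
    else:
        stat = diff**2 / var
    if stat == 0.0:
        p = 1.0
    elif not np.isfinite(stat):
        p = 0.0
    elif var_rep > 0:
        # the between-repeat variance is estimated with few degrees of
        # freedom; a Satterthwaite F reference keeps the null calibrated
        # (falls back to chi2(1) as the effective df grows)
        nu = var**2 / (var_rep**2 / (n_diff - 1))
        p = float(f_dist.sf(stat, 1, nu))
    else:
        p = float(chi2.sf(stat, df=1))
    return ComparisonResult(
        statistic=float(stat), p_value=p, method=method, auc_a=auc_a, auc_b=auc_b
    )


# ---------------------------------------------------------------------------
# study-table orchestration


def single_feature_screen(
    cohort: pd.DataFrame,
    outcome: OutcomeMode | str = OutcomeMode.CLINIC,
    config: CVConfig = CVConfig(),
    features: list[str] | None = None,
) -> pd.DataFrame:
    """AUC of each grade feature alone (the single-feature screening table)."""
    features = features or list(GRADE_COLUMNS)
    labels = derive_labels(cohort, outcome)
    keep = labels.notna()
    sub = cohort.loc[keep]
    y = labels[keep].astype(int).to_numpy()
    rows = []
    for name in features:
        res = run_repeated_cv(sub[[name]].to_numpy(float), y, config)
        rows.append(
            {
                "feature": name,
                "auc_pct": 100 * res.auc_mean,
                "auc_sd_pct": 100 * res.auc_sd,
                "n": len(y),
            }
        )
    return pd.DataFrame(rows)


def evaluate_spec(
    cohort: pd.DataFrame,
    spec: FeatureSetSpec,
    outcome: OutcomeMode | str,
    config: CVConfig,
    automated: pd.DataFrame | None = None,
    remove_widespread: bool = False,
) -> ROCResult:
    """Labels + exclusions + feature assembly + repeated CV for one cell
    of the study design."""
    df = cohort
    if remove_widespread:
        df, _ = filter_widespread(df)
    labels = derive_labels(df, outcome)
    keep = labels.notna()
    df = df.loc[keep]
    y = labels[keep].astype(int).to_numpy()
    ids = df.index.to_numpy()
    if spec.kind is FeatureSet.BEST_AUTO:
        if automated is None:
            raise ValueError("BEST_AUTO requires the automated feature table")
        variants = {}
        for kind in (FeatureSet.AUTO_SHAPE, FeatureSet.AUTO_TEXTURE, FeatureSet.AUTO_COMBINED):
            xv, _ = assemble_features(df, FeatureSetSpec(kind), automated)
            variants[kind.value] = xv
        return run_repeated_cv_best_auto(variants, y, config, row_ids=ids)
    x, _cols = assemble_features(df, spec, automated)
    return run_repeated_cv(x, y, config, row_ids=ids)


def table_runner(
    cohort: pd.DataFrame,
    specs: list[tuple[OutcomeMode | str, FeatureSetSpec, bool]],
    config: CVConfig = CVConfig(),
    automated: pd.DataFrame | None = None,
    referent: FeatureSet = FeatureSet.MANUAL,
) -> pd.DataFrame:
    """Run a grid of (outcome, feature set, widespread-filter) cells.

    Within each outcome the referent row (MANUAL, no filter) anchors the
    p-values: paired DeLong when a cell shares the referent's rows,
    unpaired otherwise (e.g. after the widespread exclusion).
    """
    results: dict[tuple, ROCResult] = {}
    for outcome, spec, filt in specs:
        key = (OutcomeMode(outcome), spec, filt)
        results[key] = evaluate_spec(
            cohort, spec, outcome, config, automated, remove_widespread=filt
        )
    rows = []
    for (outcome, spec, filt), res in results.items():
        ref_key = (outcome, FeatureSetSpec(referent), False)
        p = np.nan
        if ref_key in results and ref_key != (outcome, spec, filt):
            ref = results[ref_key]
            same_rows = len(ref.row_ids) == len(res.row_ids) and np.all(
                ref.row_ids == res.row_ids
            )
            p = compare_auc(res, ref, paired=same_rows).p_value
        rows.append(
            {
                "outcome": outcome.value,
                "feature_set": spec.kind.value
                + (f"({spec.feature})" if spec.feature else ""),
                "widespread_removed": filt,
                "n": len(res.labels),
                "auc_pct": 100 * res.auc_mean,
                "auc_sd_pct": 100 * res.auc_sd,
                "p_vs_referent": p,
            }
        )
    return pd.DataFrame(rows)
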