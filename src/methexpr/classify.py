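"""Random-forest LOOCV classifier construction and panel selection.

The biomarker panel is built the way the source analysis style prescribes:
a random forest is fit inside every leave-one-out fold, per-feature
impurity-decrease importances are averaged across folds, features are
ranked by mean importance, and candidate panels grow one feature at a time
in rank order. Each panel size k is scored by LOOCV: every sample receives
an out-of-fold case-probability (fraction of trees voting case), the AUC is
the Mann-Whitney concordance of those scores, and the panel p-value is the
two-sided normal-approximation rank-sum test of case vs control scores.
The best panel is the smallest k attaining the maximum AUC. A fitted panel
can then be applied unchanged to an independent cohort to check disease
specificity (a near-0.5 AUC on a different disease is the desired outcome).

Reproducibility: the RNG of each fold's forest derives from the master seed
plus a hash of the held-out sample identifier (and the panel size where
applicable), and training rows are sorted by sample identifier before
fitting — so results do not depend on sample or fold order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from methexpr.dataio import ConfigError, LabeledMatrix, ProbeAnnotation

__all__ = [
    "FeatureTable",
    "PanelResult",
    "cross_cohort_validate",
    "dominant_region_features",
    "expression_features",
    "incremental_panel",
    "loocv_scores",
    "methylation_features",
    "rank_importance",
    "roc_auc",
]

DEFAULT_N_TREES = 500

_SOURCES = ("expression_log2", "beta_all_regions", "beta_dominant_regions")


@dataclass
class FeatureTable:
    """Samples x features design matrix with case/control labels."""

    X: pd.DataFrame
    y: pd.Series
    source: str = "expression_log2"

    def __post_init__(self) -> None:
        self.y = pd.Series(self.y).loc[self.X.index]
        if self.X.isna().to_numpy().any():
            raise ConfigError("feature table contains missing values; impute or drop upstream")
        bad = set(self.y) - {"case", "control"}
        if bad:
            raise ConfigError(f"labels must be case/control; found {sorted(bad)}")
        for label in ("case", "control"):
            if (self.y == label).sum() < 2:
                raise ConfigError(f"need >=2 samples of class {label!r}")

    def with_gender(self, gender: pd.Series) -> "FeatureTable":
        """Append gender as a 0/1 feature column (male=1)."""
        X = self.X.copy()
        X["gender"] = (pd.Series(gender).loc[self.X.index] == "male").astype(float)
        return FeatureTable(X=X, y=self.y, source=self.source)


def expression_features(expression: LabeledMatrix, genes: Sequence[str]) -> FeatureTable:
    """Feature table of log2 expression for the given genes."""
    missing = [g for g in genes if g not in expression.feature_ids]
    if missing:
        raise ConfigError(f"genes absent from expression matrix: {missing[:5]}")
    X = expression.values.loc[list(genes)].T
    return FeatureTable(X=X, y=expression.group, source="expression_log2")


def methylation_features(beta_means: pd.DataFrame, group: pd.Series, genes: Sequence[str]) -> FeatureTable:
    """Feature table of region-averaged beta values (all-region aggregate)."""
    missing = [g for g in genes if g not in beta_means.index]
    if missing:
        raise ConfigError(f"genes absent from methylation aggregate: {missing[:5]}")
    X = beta_means.loc[list(genes)].T
    return FeatureTable(X=X, y=group, source="beta_all_regions")


def dominant_region_features(
    methylation: LabeledMatrix,
    annotation: ProbeAnnotation,
    dominant: Mapping[str, Sequence[str]],
) -> FeatureTable:
    """Per-gene mean beta over each gene's dominant-region CpGs only."""
    pairs = annotation.assignments
    cols = {}
    for gene, regions in dominant.items():
        probes = pairs[(pairs["gene"] == gene) & (pairs["region"].isin(list(regions)))][
            "probe_id"
        ].unique()
        probes = [p for p in probes if p in methylation.feature_ids]
        if not probes:
            raise ConfigError(f"gene {gene!r}: no probes in dominant regions {list(regions)}")
        cols[gene] = methylation.values.loc[probes].mean(axis=0)
    X = pd.DataFrame(cols)
    return FeatureTable(X=X, y=methylation.group, source="beta_dominant_regions")


def _fold_seed(seed: int, *tokens) -> int:
    """Deterministic 31-bit seed from the master seed and arbitrary tokens."""
    payload = ":".join(str(t) for t in (seed, *tokens)).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF


def _fit_forest(X: pd.DataFrame, y: pd.Series, n_trees: int, rs: int) -> RandomForestClassifier:
    order = X.index.sort_values()
    Xo, yo = X.loc[order], y.loc[order]
    if yo.nunique() < 2:
        raise ConfigError("training fold contains a single class")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=rs, n_jobs=1
    )
    rf.fit(Xo.to_numpy(), (yo == "case").to_numpy(dtype=int))
    return rf


def rank_importance(
    table: FeatureTable, n_trees: int = DEFAULT_N_TREES, seed: int = 0
) -> pd.DataFrame:
    """Mean per-fold impurity-decrease importance, ranked descending.

    One forest is fit per LOOCV fold on the n-1 training samples; the
    per-feature importances are averaged over folds. Ties in mean importance
    break by feature identifier. Returns a DataFrame indexed by feature with
    columns mean_importance and rank (1-based).
    """
    importances = np.zeros(table.X.shape[1])
    for sample in table.X.index:
        train = table.X.index != sample
        rf = _fit_forest(
            table.X.loc[train], table.y.loc[train], n_trees, _fold_seed(seed, "imp", sample)
        )
        importances += rf.feature_importances_
    importances /= len(table.X.index)
    # stable tie-break by feature id: sort ids first, then by importance
    out = (
        pd.DataFrame({"mean_importance": importances}, index=table.X.columns)
        .sort_index()
        .sort_values("mean_importance", ascending=False, kind="mergesort")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def loocv_scores(
    table: FeatureTable,
    features: Sequence[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    _seed_tokens: tuple = (),
) -> pd.Series:
    """Out-of-fold case-probability for every sample.

    Each sample is scored by a forest trained on all other samples using
    only ``features``; the score is the fraction of trees voting case.
    """
    features = list(features)
    missing = [f for f in features if f not in table.X.columns]
    if missing:
        raise ConfigError(f"features absent from table: {missing[:5]}")
    X = table.X.loc[:, features]
    scores = pd.Series(np.nan, index=X.index, dtype=float)
    for sample in X.index:
        train = X.index != sample
        rf = _fit_forest(
            X.loc[train],
            table.y.loc[train],
            n_trees,
            _fold_seed(seed, *_seed_tokens, "fold", sample),
        )
        scores.loc[sample] = rf.predict_proba(X.loc[[sample]].to_numpy())[0, 1]
    return scores


def roc_auc(scores: pd.Series, labels: pd.Series) -> tuple[pd.DataFrame, float, float]:
    """ROC points, Mann-Whitney AUC (ties = 1/2), and rank-sum p-value.

    The p-value is the two-sided normal-approximation Wilcoxon rank-sum test
    with tie correction, comparing case scores against control scores.
    """
    labels = pd.Series(labels).loc[scores.index]
    y = (labels == "case").to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ConfigError("roc_auc needs both classes present")
    s = scores.to_numpy(dtype=float)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    case_scores, ctrl_scores = s[y == 1], s[y == 0]
    if np.all(s == s[0]):
        p_value = 1.0
    else:
        p_value = float(
            sps.mannwhitneyu(
                case_scores, ctrl_scores, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return points, auc, p_value


@dataclass
class PanelResult:
    """Importance-ranked incremental panel selection outcome."""

    ranked_features: list[str]
    auc_by_k: dict[int, float]
    best_k: int
    best_panel: list[str]
    roc_points: pd.DataFrame = field(repr=False)
    auc: float = float("nan")
    p_value: float = float("nan")
    scores: pd.Series = field(default=None, repr=False)
    seed: int = 0


def incremental_panel(
    table: FeatureTable,
    ranked_features: Sequence[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_k: int | None = None,
) -> PanelResult:
    """Grow the panel one feature at a time in importance order.

    For k = 1..K the top-k features are LOOCV-scored and the AUC recorded;
    the best panel is the smallest k achieving the maximum AUC. Per-(k, fold)
    RNG streams derive from the master seed, so every auc_by_k entry is
    independently reproducible.
    """
    ranked_features = list(ranked_features)
    if not ranked_features:
        raise ConfigError("ranked_features must be non-empty")
    K = len(ranked_features) if max_k is None else min(max_k, len(ranked_features))
    auc_by_k: dict[int, float] = {}
    scores_by_k: dict[int, pd.Series] = {}
    for k in range(1, K + 1):
        scores = loocv_scores(
            table, ranked_features[:k], n_trees=n_trees, seed=seed, _seed_tokens=("k", k)
        )
        _, auc, _ = roc_auc(scores, table.y)
        auc_by_k[k] = auc
        scores_by_k[k] = scores
    best_k = min(auc_by_k, key=lambda k: (-auc_by_k[k], k))
    best_scores = scores_by_k[best_k]
    roc_points, auc, p_value = roc_auc(best_scores, table.y)
    return PanelResult(
        ranked_features=ranked_features,
        auc_by_k=auc_by_k,
        best_k=best_k,
        best_panel=ranked_features[:best_k],
        roc_points=roc_points,
        auc=auc,
        p_value=p_value,
        scores=best_scores,
        seed=seed,
    )


def cross_cohort_validate(
    train_table: FeatureTable,
    panel: Sequence[str],
    other_table: FeatureTable,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> tuple[float, float]:
    """Score an independent cohort with a panel model fit on the full training cohort.

    Returns (AUC, rank-sum p-value) against the other cohort's labels. Every
    panel feature must exist in the other cohort's table.
    """
    panel = list(panel)
    missing = [f for f in panel if f not in other_table.X.columns]
    if missing:
        raise ConfigError(f"other cohort is missing panel features: {missing}")
    missing_train = [f for f in panel if f not in train_table.X.columns]
    if missing_train:
        raise ConfigError(f"training cohort is missing panel features: {missing_train}")
    rf = _fit_forest(
        train_table.X.loc[:, panel], train_table.y, n_trees, _fold_seed(seed, "xval")
    )
    scores = pd.Series(
        rf.predict_proba(other_table.X.loc[:, panel].to_numpy())[:, 1],
        index=other_table.X.index,
    )
    _, auc, p_value = roc_auc(scores, other_table.y)
    return auc, p_value
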