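"""Region-level methylation summarization and differential calling.

Methylation arrives as beta values (the methylated fraction at a CpG,
bounded in [0, 1]). Statistics are computed on the M-value scale,
m = log2(b / (1 - b)), which is unbounded and closer to homoscedastic, while
effect sizes are reported as delta-beta (case mean minus control mean on the
beta scale), which is the biologically interpretable quantity. A gene's
methylation level at a region selector is the arithmetic mean beta over the
CpGs assigned to that gene with that region label (or over all its CpGs for
the pooled ``ALL`` selector).

A feature (gene at a selector, or intergenic CpG) is called differentially
methylated only when both criteria hold: its delta-beta falls below the 0.1
quantile or above the 0.8 quantile of the delta-beta distribution across all
features, and its BH-adjusted M-value p-value is below alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from methexpr.dataio import REGIONS, ConfigError, LabeledMatrix, ProbeAnnotation
from methexpr.diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_REGIONS",
    "BETA_EPS",
    "ContingencyTable2x2",
    "RegionLevel",
    "aggregate_region",
    "beta_to_m",
    "call_dmfs",
    "chi_square_2x2",
    "decile_thresholds",
    "delta_beta",
    "enhancer_enrichment",
    "m_to_beta",
]

#: Pooled selector: every CpG assigned to the gene, regardless of region.
ALL_REGIONS = "ALL"

#: Beta values are clamped into [eps, 1-eps] before the logit.
BETA_EPS = 1e-6

_SELECTORS = REGIONS + (ALL_REGIONS,)


def beta_to_m(beta):
    """logit2 transform: m = log2(beta / (1 - beta)), elementwise.

    Betas are clamped to [1e-6, 1 - 1e-6] first; background-normalized
    arrays can touch 0 or 1 exactly.
    """
    arr = np.asarray(beta, dtype=float)
    if not np.isfinite(arr[~np.isnan(arr)]).all():
        raise ValueError("beta_to_m: non-finite input")
    clamped = np.clip(arr, BETA_EPS, 1.0 - BETA_EPS)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if arr.shape else float(m)


def m_to_beta(m_value):
    """Inverse logit2: beta = 2^m / (2^m + 1), elementwise."""
    arr = np.asarray(m_value, dtype=float)
    if not np.isfinite(arr[~np.isnan(arr)]).all():
        raise ValueError("m_to_beta: non-finite input")
    with np.errstate(over="ignore"):
        beta = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m_value, pd.DataFrame):
        return pd.DataFrame(beta, index=m_value.index, columns=m_value.columns)
    if isinstance(m_value, pd.Series):
        return pd.Series(beta, index=m_value.index)
    return beta if arr.shape else float(beta)


@dataclass
class RegionLevel:
    """Per-gene mean beta at one region selector.

    ``beta_means`` is genes x samples; ``probe_counts`` gives the number of
    CpGs contributing to each retained gene (always >= 1 — genes with no
    qualifying probe are omitted). Group/gender labels are carried along so
    the result can feed straight into the differential machinery.
    """

    selector: str
    beta_means: pd.DataFrame
    probe_counts: pd.Series
    group: pd.Series
    gender: pd.Series | None = None

    def as_matrix(self) -> LabeledMatrix:
        return LabeledMatrix(
            values=self.beta_means, scale="beta", group=self.group, gender=self.gender
        )

    def m_matrix(self) -> LabeledMatrix:
        return LabeledMatrix(
            values=beta_to_m(self.beta_means),
            scale="log2_expression",  # unbounded scale; reuse validation rules
            group=self.group,
            gender=self.gender,
        )


def aggregate_region(
    methylation: LabeledMatrix,
    annotation: ProbeAnnotation,
    selector: str,
) -> RegionLevel:
    """Average beta over each gene's CpGs at ``selector``.

    A probe assigned to k genes contributes to all k gene aggregates. For
    ``ALL`` each distinct CpG of a gene counts once even if the manifest
    lists it under several region labels for that gene. Missing betas are
    skipped per sample; genes with no qualifying probes are omitted.
    """
    if selector not in _SELECTORS:
        raise ConfigError(f"selector must be one of {_SELECTORS}, got {selector!r}")
    pairs = annotation.assignments
    if selector != ALL_REGIONS:
        pairs = pairs[pairs["region"] == selector]
    pairs = pairs.drop_duplicates(subset=["probe_id", "gene"])
    pairs = pairs[pairs["probe_id"].isin(methylation.feature_ids)]
    if pairs.empty:
        warnings.warn(f"no gene has probes for selector {selector!r}", stacklevel=2)
        empty = pd.DataFrame(columns=methylation.sample_ids, dtype=float)
        return RegionLevel(
            selector=selector,
            beta_means=empty,
            probe_counts=pd.Series(dtype=int),
            group=methylation.group,
            gender=methylation.gender,
        )
    probe_vals = methylation.values.loc[pairs["probe_id"]]
    grouped = probe_vals.groupby(pairs["gene"].to_numpy())
    beta_means = grouped.mean()
    beta_means.index.name = "gene"
    counts = pairs.groupby("gene").size().reindex(beta_means.index)
    return RegionLevel(
        selector=selector,
        beta_means=beta_means,
        probe_counts=counts,
        group=methylation.group,
        gender=methylation.gender,
    )


def delta_beta(level: RegionLevel | LabeledMatrix) -> pd.Series:
    """Case-minus-control mean beta per feature (negative = hypo in cases)."""
    matrix = level.as_matrix() if isinstance(level, RegionLevel) else level
    case = matrix.values.loc[:, matrix.case_ids]
    ctrl = matrix.values.loc[:, matrix.control_ids]
    if case.shape[1] == 0 or ctrl.shape[1] == 0:
        raise ConfigError("delta_beta needs both groups present")
    return case.mean(axis=1, skipna=True) - ctrl.mean(axis=1, skipna=True)


def decile_thresholds(
    deltas, low_q: float = 0.1, high_q: float = 0.8
) -> tuple[float, float]:
    """The (0.1, 0.8) quantiles of the all-feature delta-beta distribution.

    Quantiles use linear interpolation of order statistics (h = (n-1)q).
    Requires at least 10 finite values.
    """
    arr = np.asarray(deltas, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 10:
        raise ConfigError(f"decile_thresholds needs >=10 finite deltas, got {arr.size}")
    low, high = np.quantile(arr, [low_q, high_q], method="linear")
    return float(low), float(high)


def call_dmfs(
    m_stats: pd.DataFrame,
    deltas: pd.Series,
    thresholds: tuple[float, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dual-criterion differential methylation call.

    ``m_stats`` comes from ``fit_group_model`` on the M-values of the same
    feature list (genes at one selector, or intergenic CpGs); ``deltas`` is
    the matching delta-beta series. Significant iff (delta < low OR
    delta > high) AND BH-adjusted p < alpha, all strict. The returned
    DiffTable stores delta-beta in ``effect`` and keeps the M-scale effect
    as ``m_effect``; direction is hypo (delta < low) or hyper (delta > high).
    """
    if set(m_stats.index) != set(deltas.index):
        raise ConfigError("call_dmfs: m_stats and deltas cover different features")
    low, high = thresholds
    deltas = deltas.loc[m_stats.index]
    out = pd.DataFrame(index=m_stats.index)
    out["effect"] = deltas
    out["m_effect"] = m_stats["effect"]
    out["t_stat"] = m_stats["t_stat"]
    out["p_value"] = m_stats["p_value"]
    out["adj_p"] = bh_adjust(m_stats["p_value"].to_numpy())
    extreme_low = deltas < low
    extreme_high = deltas > high
    out["significant"] = (extreme_low | extreme_high) & (out["adj_p"] < alpha)
    out["direction"] = np.where(
        out["significant"] & extreme_low,
        "hypo",
        np.where(out["significant"] & extreme_high, "hyper", "none"),
    )
    return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for the enhancer-enrichment test.

    Rows: differential / non-differential features; columns: enhancer /
    non-enhancer probes. (a, b) is the differential row.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ConfigError(f"negative count in 2x2 table: {counts}")
        if sum(counts) == 0:
            raise ConfigError("empty 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table, df = 1.

    No continuity correction by default. P-values that underflow to zero are
    reported as the smallest positive normal float so that bounds like
    "p < 2.2e-16" remain decidable.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ConfigError("degenerate table: a row or column marginal is zero")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=yates)
    p = float(p)
    if p <= 0.0:
        p = float(np.finfo(float).tiny)
    return float(stat), p


def enhancer_enrichment(
    dmc_calls: pd.DataFrame,
    annotation: ProbeAnnotation,
    yates: bool = False,
) -> tuple[ContingencyTable2x2, float, float]:
    """Test whether differential intergenic CpGs are enriched for enhancers.

    ``dmc_calls`` is a DiffTable over intergenic probes. Builds the 2x2
    table (differential/non-differential x enhancer/non-enhancer) and runs
    the Pearson chi-square test.
    """
    probe_ids = dmc_calls.index
    not_intergenic = [
        p for p in probe_ids if not bool(annotation.probes.loc[p, "intergenic"])
    ]
    if not_intergenic:
        raise ConfigError(
            f"enhancer_enrichment expects intergenic probes only; offenders: {not_intergenic[:5]}"
        )
    enh = annotation.enhancer_flags(probe_ids).to_numpy(dtype=bool)
    sig = dmc_calls["significant"].to_numpy(dtype=bool)
    table = ContingencyTable2x2(
        a=int((sig & enh).sum()),
        b=int((sig & ~enh).sum()),
        c=int((~sig & enh).sum()),
        d=int((~sig & ~enh).sum()),
    )
    stat, p = chi_square_2x2(table, yates=yates)
    return table, stat, p
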