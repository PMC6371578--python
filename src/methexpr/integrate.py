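"""Integration of differential expression and differential methylation.

Genes significant in both analyses fall into four overlap classes from the
cross of their directions: hypo-up (hypo-methylated and upregulated — the
candidate biomarker class), hyper-down, hyper-up, and hypo-down. For each
gene of interest the dominant methylation-altered regions are the region(s)
whose delta-beta lies strictly within 0.005 of the gene's minimum
delta-beta; a gene may have one or several dominant regions. Finally,
expression can be correlated against region-level methylation on matched
samples (Pearson, two-sided t-based p), where the working expectation is a
negative correlation for hypo-up genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from methexpr.dataio import REGIONS, ConfigError, LabeledMatrix
from methexpr.diffmeth import RegionLevel

__all__ = [
    "DOMINANT_TOLERANCE",
    "DominantRegionCall",
    "classify_overlap",
    "dominant_regions",
    "dominant_regions_table",
    "expr_meth_correlation",
    "overlap_summary",
    "region_delta_table",
]

#: Regions whose delta-beta is within this of the minimum are dominant.
DOMINANT_TOLERANCE = 0.005

_CLASS_OF = {
    ("up", "hypo"): "hypo-up",
    ("down", "hyper"): "hyper-down",
    ("up", "hyper"): "hyper-up",
    ("down", "hypo"): "hypo-down",
}


def classify_overlap(degs: pd.DataFrame, dmgs: pd.DataFrame) -> pd.DataFrame:
    """Cross significant DEG and DMG calls into the four overlap classes.

    Returns one row per gene significant in both tables, with columns
    deg_direction, dmg_direction, overlap_class, and the expression and
    methylation effects. Per-class counts come from :func:`overlap_summary`.
    """
    deg_sig = degs[degs["significant"]]
    dmg_sig = dmgs[dmgs["significant"]]
    shared = deg_sig.index.intersection(dmg_sig.index)
    out = pd.DataFrame(index=shared)
    out["deg_direction"] = deg_sig.loc[shared, "direction"]
    out["dmg_direction"] = dmg_sig.loc[shared, "direction"]
    out["overlap_class"] = [
        _CLASS_OF[(e, m)] for e, m in zip(out["deg_direction"], out["dmg_direction"])
    ]
    out["log2fc"] = deg_sig.loc[shared, "effect"]
    out["delta_beta"] = dmg_sig.loc[shared, "effect"]
    return out


def overlap_summary(overlap: pd.DataFrame) -> dict:
    """Per-class counts and the hypo-up fraction of the overlap."""
    counts = {cls: int((overlap["overlap_class"] == cls).sum()) for cls in _CLASS_OF.values()}
    total = len(overlap)
    return {
        "counts": counts,
        "total": total,
        "hypo_up_fraction": counts["hypo-up"] / total if total else float("nan"),
    }


@dataclass(frozen=True)
class DominantRegionCall:
    """Dominant methylation-altered regions of one gene."""

    gene_id: str
    deltas: dict[str, float]
    dominant: tuple[str, ...]
    tolerance: float = DOMINANT_TOLERANCE


def dominant_regions(
    gene_id: str,
    deltas: Mapping[str, float],
    tolerance: float = DOMINANT_TOLERANCE,
) -> DominantRegionCall:
    """Regions within ``tolerance`` (strict) of the gene's minimum delta-beta.

    ``deltas`` maps region label -> delta-beta for the regions where the
    gene has probes; absent regions are never dominant. The argmin region is
    always dominant (its gap is zero).
    """
    clean = {r: float(v) for r, v in deltas.items() if np.isfinite(v)}
    if not clean:
        raise ConfigError(f"gene {gene_id!r}: no region deltas available")
    bad = set(clean) - set(REGIONS)
    if bad:
        raise ConfigError(f"gene {gene_id!r}: unknown regions {sorted(bad)}")
    min_delta = min(clean.values())
    dominant = tuple(r for r in REGIONS if r in clean and clean[r] - min_delta < tolerance)
    return DominantRegionCall(gene_id=gene_id, deltas=clean, dominant=dominant, tolerance=tolerance)


def region_delta_table(
    region_levels: Mapping[str, RegionLevel],
    genes: list[str] | pd.Index | None = None,
) -> pd.DataFrame:
    """Genes x regions table of delta-beta values (NaN where no probes).

    ``region_levels`` maps each of the six region labels to its
    :class:`RegionLevel`; selectors other than the six labels are ignored.
    """
    from methexpr.diffmeth import delta_beta  # local import avoids cycle at load

    cols = {}
    for region in REGIONS:
        if region not in region_levels:
            continue
        level = region_levels[region]
        if level.beta_means.empty:
            continue
        cols[region] = delta_beta(level)
    table = pd.DataFrame(cols)
    if genes is not None:
        table = table.reindex([g for g in genes if g in table.index])
    return table


def dominant_regions_table(
    delta_table: pd.DataFrame,
    tolerance: float = DOMINANT_TOLERANCE,
) -> pd.DataFrame:
    """Apply :func:`dominant_regions` to every row of a genes x regions table."""
    rows = []
    for gene, row in delta_table.iterrows():
        call = dominant_regions(gene, row.dropna().to_dict(), tolerance=tolerance)
        record = {"gene_id": gene, "dominant_regions": ";".join(call.dominant)}
        for region in REGIONS:
            record[f"delta_{region}"] = call.deltas.get(region, np.nan)
        rows.append(record)
    return pd.DataFrame(rows)


def expr_meth_correlation(
    expression: LabeledMatrix,
    region_levels: Mapping[str, RegionLevel],
    genes: list[str],
    n_per_group: int,
    seed: int,
) -> pd.DataFrame:
    """Pearson correlation of expression vs region methylation per gene.

    Draws ``n_per_group`` cases and controls without replacement (matched
    samples: expression and methylation must share sample identifiers), then
    computes Pearson r and the two-sided t-based p-value for every
    (gene, region) pair with data. Returns a long table with columns
    gene_id, region, pearson_r, p_value.

    Summary statistics of interest downstream: the fraction of negative r
    across pairs and the genes with any region at p < 0.05.
    """
    rng = np.random.default_rng(seed)
    case_ids = list(expression.case_ids)
    ctrl_ids = list(expression.control_ids)
    if n_per_group > len(case_ids) or n_per_group > len(ctrl_ids):
        raise ConfigError(
            f"n_per_group={n_per_group} exceeds availability "
            f"({len(case_ids)} cases, {len(ctrl_ids)} controls)"
        )
    chosen = list(rng.choice(case_ids, size=n_per_group, replace=False)) + list(
        rng.choice(ctrl_ids, size=n_per_group, replace=False)
    )
    rows = []
    expr_sub = expression.values.loc[:, chosen]
    for region in REGIONS:
        if region not in region_levels:
            continue
        level = region_levels[region]
        missing_samples = [s for s in chosen if s not in level.beta_means.columns]
        if missing_samples:
            raise ConfigError(
                f"methylation misses samples present in expression: {missing_samples[:5]}"
            )
        meth_sub = level.beta_means.loc[:, chosen]
        for gene in genes:
            if gene not in meth_sub.index or gene not in expr_sub.index:
                continue
            x = expr_sub.loc[gene].to_numpy(dtype=float)
            y = meth_sub.loc[gene].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            r, p = sps.pearsonr(x[ok], y[ok])
            rows.append({"gene_id": gene, "region": region, "pearson_r": r, "p_value": p})
    return pd.DataFrame(rows, columns=["gene_id", "region", "pearson_r", "p_value"])
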