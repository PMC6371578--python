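"""Paired synthetic expression + methylation cohorts with planted truth.

The generator emulates the statistical structure of a two-cohort blood
study: a log2-scale expression matrix (genes x samples) and a 450K-style
beta-value matrix (CpG probes x samples) over case/control samples, with a
manifest-like probe annotation. Planted signal genes belong to one of four
classes (hypo-up, hyper-down, hypo-down, hyper-up) combining an expression
shift with a methylation shift concentrated in designated dominant regions;
planted differential intergenic CpGs are enriched for enhancer flags.

Methylation effects and noise are applied on the M-value (logit2) scale and
back-transformed, which keeps every beta strictly inside (0, 1). The
M-scale shift for a planted probe is calibrated per probe so that the
noiseless case-control beta difference equals the configured ``meth_effect``;
with Gaussian M-scale noise the realized group mean-beta difference stays
close to that target for mid-range baselines. Probes of one gene-region
share a common baseline (plus a small per-probe jitter), so region
averaging acts on correlated CpGs as it does on real arrays.

Everything derives from one master seed through named substreams, so an
identical configuration reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methexpr.dataio import (
    REGIONS,
    ConfigError,
    LabeledMatrix,
    ProbeAnnotation,
    read_annotation,
    read_matrix,
    read_metadata,
    read_table,
    write_matrix,
    write_table,
)
from methexpr.diffmeth import beta_to_m, m_to_beta

__all__ = ["SimConfig", "SyntheticCohort", "generate_cohort", "write_cohort", "read_cohort"]

PLANTED_CLASSES = ("hypo-up", "hyper-down", "hypo-down", "hyper-up")

#: sd of the per-probe M-scale jitter around the shared gene-region baseline.
_PROBE_JITTER_SD = 0.15

#: fraction of planted differential intergenic CpGs that are hypo-methylated
#: (blood methylation studies of this design report ~80% hypo).
_INTERGENIC_HYPO_FRACTION = 0.8

#: fraction of genes receiving the gender shift when gender_effect != 0.
_GENDER_GENE_FRACTION = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic paired cohort.

    Defaults describe a desk-scale study with detectable planted signal:
    200 cases vs 200 controls, 2000 genes with two CpGs per gene region,
    85 planted hypo-methylated/upregulated genes with a +0.3 log2 expression
    shift and a -0.05 beta shift in their dominant regions, and intergenic
    CpGs whose planted differential subset is enhancer-enriched with an odds
    multiplier matching real-array magnitudes.

    ``dominant_regions`` lists, per planted gene in planting order, the
    region labels that receive the full ``meth_effect`` shift (non-dominant
    regions get ``meth_offregion_effect``). The default ``None`` plants a
    gene-wide shift: all six regions dominant, so the all-region aggregate
    carries the full beta-scale effect.
    """

    n_case: int = 200
    n_control: int = 200
    n_genes: int = 2000
    probes_per_region: int = 2
    n_intergenic: int = 1000
    frac_enhancer_intergenic: float = 0.32
    n_hypo_up: int = 85
    n_hyper_down: int = 0
    n_hypo_down: int = 0
    n_hyper_up: int = 0
    expr_effect: float = 0.3
    meth_effect: float = 0.05
    meth_offregion_effect: float = 0.0
    dominant_regions: tuple[tuple[str, ...], ...] | None = None
    planted_gene_indices: tuple[int, ...] | None = None
    n_diff_intergenic: int = 200
    enhancer_enrichment_odds: float = 2.2
    expr_noise_sd: float = 0.5
    meth_noise_sd: float = 0.5
    baseline_beta_range: tuple[float, float] = (0.2, 0.8)
    gender_effect: float = 0.0
    seed: int = 0

    @property
    def n_planted(self) -> int:
        return self.n_hypo_up + self.n_hyper_down + self.n_hypo_down + self.n_hyper_up

    def validate(self) -> None:
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_genes": self.n_genes,
            "probes_per_region": self.probes_per_region,
            "n_intergenic": self.n_intergenic,
            "n_hypo_up": self.n_hypo_up,
            "n_hyper_down": self.n_hyper_down,
            "n_hypo_down": self.n_hypo_down,
            "n_hyper_up": self.n_hyper_up,
            "n_diff_intergenic": self.n_diff_intergenic,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_planted > self.n_genes:
            raise ConfigError(
                f"planted classes total {self.n_planted} but n_genes={self.n_genes}"
            )
        if self.n_diff_intergenic > self.n_intergenic:
            raise ConfigError(
                f"n_diff_intergenic={self.n_diff_intergenic} exceeds n_intergenic={self.n_intergenic}"
            )
        if not 0.0 <= self.frac_enhancer_intergenic <= 1.0:
            raise ConfigError(
                f"frac_enhancer_intergenic must be in [0, 1], got {self.frac_enhancer_intergenic}"
            )
        lo, hi = self.baseline_beta_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError(
                f"baseline_beta_range must satisfy 0 < low < high < 1, got {self.baseline_beta_range}"
            )
        for name in ("expr_noise_sd", "meth_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.enhancer_enrichment_odds <= 0:
            raise ConfigError("enhancer_enrichment_odds must be positive")
        if self.planted_gene_indices is not None:
            idx = self.planted_gene_indices
            if len(idx) != self.n_planted:
                raise ConfigError(
                    f"planted_gene_indices has {len(idx)} entries for {self.n_planted} planted genes"
                )
            if len(set(idx)) != len(idx):
                raise ConfigError("planted_gene_indices contains duplicates")
            if any(i < 0 or i >= self.n_genes for i in idx):
                raise ConfigError("planted_gene_indices out of range for n_genes")
        if self.dominant_regions is not None:
            if len(self.dominant_regions) != self.n_planted:
                raise ConfigError(
                    f"dominant_regions has {len(self.dominant_regions)} entries "
                    f"for {self.n_planted} planted genes"
                )
            for regions in self.dominant_regions:
                if not regions:
                    raise ConfigError("dominant_regions entries must list >=1 region")
                bad = set(regions) - set(REGIONS)
                if bad:
                    raise ConfigError(f"dominant_regions: unknown region labels {sorted(bad)}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expression: LabeledMatrix
    methylation: LabeledMatrix
    annotation: ProbeAnnotation
    metadata: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_intergenic: pd.DataFrame
    config: SimConfig = field(repr=False)

    @property
    def planted_genes(self) -> pd.DataFrame:
        return self.truth_genes[self.truth_genes["class"] != "none"]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _class_sign(cls: str) -> tuple[int, int]:
    """(expression sign, methylation sign) for a planted class."""
    expr = +1 if cls.endswith("up") else -1
    meth = -1 if cls.startswith("hypo") else +1
    return expr, meth


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a paired cohort per ``config`` (deterministic in the seed)."""
    config.validate()
    (
        rng_samples,
        rng_plant,
        rng_expr,
        rng_meth_base,
        rng_meth_noise,
        rng_intergenic,
        rng_gender_genes,
    ) = _substreams(config.seed, 7)

    n_samples = config.n_case + config.n_control
    sample_ids = [f"case_{i+1:04d}" for i in range(config.n_case)] + [
        f"ctrl_{i+1:04d}" for i in range(config.n_control)
    ]
    group = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=sample_ids
    )
    gender_pool = np.array(["male", "female"] * (n_samples // 2 + 1))[:n_samples]
    gender = pd.Series(rng_samples.permutation(gender_pool), index=sample_ids)
    case_mask = (group == "case").to_numpy(dtype=float)
    male_mask = (gender == "male").to_numpy(dtype=float)

    gene_ids = np.array([f"G{i+1:05d}" for i in range(config.n_genes)])

    # planted classes and dominant regions
    classes = np.full(config.n_genes, "none", dtype=object)
    if config.planted_gene_indices is not None:
        planted_idx = np.array(config.planted_gene_indices, dtype=int)
    else:
        planted_idx = rng_plant.choice(config.n_genes, size=config.n_planted, replace=False)
    planted_idx = np.sort(planted_idx)
    labels = (
        ["hypo-up"] * config.n_hypo_up
        + ["hyper-down"] * config.n_hyper_down
        + ["hypo-down"] * config.n_hypo_down
        + ["hyper-up"] * config.n_hyper_up
    )
    classes[planted_idx] = labels
    if config.dominant_regions is not None:
        dominant = [tuple(r) for r in config.dominant_regions]
    else:
        # default: gene-wide shift — every region of a planted gene moves by
        # meth_effect, so the all-region aggregate carries the full effect
        dominant = [tuple(REGIONS) for _ in range(config.n_planted)]
    dominant_by_gene: dict[int, tuple[str, ...]] = dict(zip(planted_idx, dominant))

    # ---- expression ----------------------------------------------------
    baseline = rng_expr.uniform(4.0, 10.0, size=config.n_genes)
    expr_sign = np.zeros(config.n_genes)
    for gi in planted_idx:
        expr_sign[gi] = _class_sign(classes[gi])[0]
    expr = (
        baseline[:, None]
        + config.expr_effect * expr_sign[:, None] * case_mask[None, :]
        + rng_expr.normal(0.0, config.expr_noise_sd, size=(config.n_genes, n_samples))
    )
    if config.gender_effect != 0.0:
        n_gender_genes = max(1, int(round(_GENDER_GENE_FRACTION * config.n_genes)))
        gender_genes = rng_gender_genes.choice(
            config.n_genes, size=n_gender_genes, replace=False
        )
        expr[gender_genes] += config.gender_effect * male_mask[None, :]
    expression = LabeledMatrix(
        values=pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        scale="log2_expression",
        group=group,
        gender=gender,
    )

    # ---- genic methylation ---------------------------------------------
    ppr = config.probes_per_region
    n_genic = config.n_genes * len(REGIONS) * ppr
    probe_gene = np.repeat(np.arange(config.n_genes), len(REGIONS) * ppr)
    probe_region = np.tile(np.repeat(np.arange(len(REGIONS)), ppr), config.n_genes)
    lo, hi = config.baseline_beta_range
    region_baseline = rng_meth_base.uniform(lo, hi, size=(config.n_genes, len(REGIONS)))
    base_beta = region_baseline[probe_gene, probe_region]
    m0 = beta_to_m(base_beta) + rng_meth_base.normal(0.0, _PROBE_JITTER_SD, size=n_genic)
    base_beta_probe = m_to_beta(m0)

    # per-probe M shift calibrated so the noiseless beta difference matches
    # the configured beta-scale effect
    target_shift = np.zeros(n_genic)
    for gi in planted_idx:
        _, meth_sign = _class_sign(classes[gi])
        dom = dominant_by_gene[gi]
        mask_gene = probe_gene == gi
        for ri, region in enumerate(REGIONS):
            mask = mask_gene & (probe_region == ri)
            effect = config.meth_effect if region in dom else config.meth_offregion_effect
            if effect == 0.0:
                continue
            target_shift[mask] = meth_sign * effect
    shifted = np.clip(base_beta_probe + target_shift, 1e-4, 1.0 - 1e-4)
    delta_m = np.where(target_shift != 0.0, beta_to_m(shifted) - m0, 0.0)

    # ---- intergenic methylation ----------------------------------------
    n_ig = config.n_intergenic
    diff_idx = np.sort(rng_intergenic.choice(n_ig, size=config.n_diff_intergenic, replace=False))
    is_diff = np.zeros(n_ig, dtype=bool)
    is_diff[diff_idx] = True
    f = config.frac_enhancer_intergenic
    odds = config.enhancer_enrichment_odds
    p_enh = np.where(is_diff, (odds * f) / (1.0 - f + odds * f), f)
    enhancer_ig = rng_intergenic.random(n_ig) < p_enh
    ig_base = rng_intergenic.uniform(lo, hi, size=n_ig)
    ig_m0 = beta_to_m(ig_base) + rng_intergenic.normal(0.0, _PROBE_JITTER_SD, size=n_ig)
    ig_base_beta = m_to_beta(ig_m0)
    ig_sign = np.zeros(n_ig)
    hypo = rng_intergenic.random(config.n_diff_intergenic) < _INTERGENIC_HYPO_FRACTION
    ig_sign[diff_idx] = np.where(hypo, -1.0, +1.0)
    ig_target = ig_sign * config.meth_effect
    ig_shifted = np.clip(ig_base_beta + ig_target, 1e-4, 1.0 - 1e-4)
    ig_delta_m = np.where(ig_target != 0.0, beta_to_m(ig_shifted) - ig_m0, 0.0)

    # ---- assemble probe matrix ------------------------------------------
    all_m0 = np.concatenate([m0, ig_m0])
    all_delta = np.concatenate([delta_m, ig_delta_m])
    n_probes = n_genic + n_ig
    m_values = (
        all_m0[:, None]
        + all_delta[:, None] * case_mask[None, :]
        + rng_meth_noise.normal(0.0, config.meth_noise_sd, size=(n_probes, n_samples))
    )
    betas = m_to_beta(m_values)
    probe_ids = np.array([f"cg{i+1:07d}" for i in range(n_probes)])
    methylation = LabeledMatrix(
        values=pd.DataFrame(betas, index=probe_ids, columns=sample_ids),
        scale="beta",
        group=group,
        gender=gender,
    )

    # ---- annotation ------------------------------------------------------
    chroms = np.concatenate(
        [
            (probe_gene % 22 + 1).astype(str),
            (np.arange(n_ig) % 22 + 1).astype(str),
        ]
    )
    positions = np.arange(1, n_probes + 1) * 1000
    enhancer = np.concatenate([np.zeros(n_genic, dtype=bool), enhancer_ig])
    intergenic = np.concatenate([np.zeros(n_genic, dtype=bool), np.ones(n_ig, dtype=bool)])
    probes = pd.DataFrame(
        {"chr": chroms, "position": positions, "enhancer": enhancer, "intergenic": intergenic},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    assignments = pd.DataFrame(
        {
            "probe_id": probe_ids[:n_genic],
            "gene": gene_ids[probe_gene],
            "region": np.array(REGIONS)[probe_region],
        }
    )
    annotation = ProbeAnnotation(probes=probes, assignments=assignments)

    # ---- truth -----------------------------------------------------------
    dom_strings = np.full(config.n_genes, "", dtype=object)
    for gi in planted_idx:
        dom_strings[gi] = ";".join(dominant_by_gene[gi])
    truth_genes = pd.DataFrame(
        {"feature_id": gene_ids, "class": classes, "dominant_regions": dom_strings}
    )
    truth_intergenic = pd.DataFrame(
        {
            "feature_id": probe_ids[n_genic:],
            "differential": is_diff,
            "direction": np.where(is_diff, np.where(ig_sign < 0, "hypo", "hyper"), "none"),
        }
    )
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "group": group.to_numpy(), "gender": gender.to_numpy()}
    )
    return SyntheticCohort(
        expression=expression,
        methylation=methylation,
        annotation=annotation,
        metadata=metadata,
        truth_genes=truth_genes,
        truth_intergenic=truth_intergenic,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as the TSV file set ``dataio``/:func:`read_cohort` read."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "methylation": directory / "methylation.tsv",
        "annotation": directory / "annotation.tsv",
        "metadata": directory / "samples.tsv",
        "truth_genes": directory / "truth_genes.tsv",
        "truth_intergenic": directory / "truth_intergenic.tsv",
    }
    write_matrix(cohort.expression.values, paths["expression"])
    write_matrix(cohort.methylation.values, paths["methylation"])
    ann = cohort.annotation
    gene_lists = ann.assignments.groupby("probe_id")["gene"].agg(";".join)
    region_lists = ann.assignments.groupby("probe_id")["region"].agg(";".join)
    ann_table = pd.DataFrame(
        {
            "probe_id": ann.probes.index,
            "chr": ann.probes["chr"].to_numpy(),
            "position": ann.probes["position"].to_numpy(),
            "gene_names": gene_lists.reindex(ann.probes.index).fillna("").to_numpy(),
            "region_groups": region_lists.reindex(ann.probes.index).fillna("").to_numpy(),
            "enhancer": np.where(ann.probes["enhancer"], "TRUE", ""),
        }
    )
    write_table(ann_table, paths["annotation"])
    write_table(cohort.metadata, paths["metadata"])
    write_table(cohort.truth_genes.fillna(""), paths["truth_genes"])
    write_table(cohort.truth_intergenic, paths["truth_intergenic"])
    return paths


def read_cohort(directory: str | Path, config: SimConfig | None = None) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    metadata = read_metadata(directory / "samples.tsv")
    expression = read_matrix(directory / "expression.tsv", "log2_expression", metadata)
    methylation = read_matrix(directory / "methylation.tsv", "beta", metadata)
    annotation = read_annotation(directory / "annotation.tsv")
    truth_genes = read_table(directory / "truth_genes.tsv").fillna("")
    truth_intergenic = read_table(directory / "truth_intergenic.tsv")
    meta = metadata.reset_index()
    return SyntheticCohort(
        expression=expression,
        methylation=methylation,
        annotation=annotation,
        metadata=meta,
        truth_genes=truth_genes,
        truth_intergenic=truth_intergenic,
        config=config if config is not None else SimConfig(),
    )
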