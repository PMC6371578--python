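"""Readers, writers, and the core labeled containers.

Matrices travel as plain TSV: a header row of sample identifiers, first
column header ``ID`` holding feature identifiers. Sample metadata (group and
optional gender) lives in a sidecar TSV rather than in embedded series-matrix
headers, which keeps fixtures simple while a minimal series-matrix value
extractor remains available for real GEO downloads. Probe annotations follow
the 450K manifest convention: semicolon-delimited parallel gene/region lists,
1-based MAPINFO coordinates, and a TRUE/empty enhancer flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six manifest-defined gene-region classes, in genomic order 5' to 3'.
REGIONS: tuple[str, ...] = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: Accepted spellings for region labels (manifest files use primed forms).
_REGION_SYNONYMS: dict[str, str] = {
    "5'UTR": "5UTR",
    "3'UTR": "3UTR",
    "5UTR": "5UTR",
    "3UTR": "3UTR",
    **{r: r for r in REGIONS},
}

_ANNOTATION_ALIASES: dict[str, str] = {
    "IlmnID": "probe_id",
    "UCSC_RefGene_Name": "gene_names",
    "UCSC_RefGene_Group": "region_groups",
    "CHR": "chr",
    "MAPINFO": "position",
    "Enhancer": "enhancer",
}

SCALES = ("log2_expression", "beta")
GROUPS = ("case", "control")

#: Beta values may overshoot [0, 1] by at most this much before rejection.
BETA_CLAMP_TOL = 1e-9

#: Beta-scale probes missing in more than this fraction of samples are dropped.
MAX_MISSING_FRACTION = 0.2


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigError(ValueError):
    """Raised when a configuration value is out of its documented range."""


@dataclass
class LabeledMatrix:
    """A features x samples numeric matrix with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature identifier with one column per sample.
    scale
        ``"log2_expression"`` or ``"beta"``. Beta values must be finite and
        inside [0, 1] wherever present; NaN marks a missing measurement.
    group
        Per-sample label, ``"case"`` or ``"control"``, aligned to columns.
    gender
        Optional per-sample label in {male, female, unknown}.
    """

    values: pd.DataFrame
    scale: str
    group: pd.Series
    gender: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature identifiers: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample identifiers: {dupes[:5]}")
        self.group = pd.Series(self.group)
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise ParseError(f"samples without a group label: {missing[:5]}")
        self.group = self.group.loc[self.values.columns]
        bad = sorted(set(self.group) - set(GROUPS))
        if bad:
            raise ParseError(f"group labels must be in {GROUPS}; found {bad}")
        if self.gender is not None:
            self.gender = pd.Series(self.gender).reindex(self.values.columns).fillna("unknown")
        if not all(np.issubdtype(d, np.number) for d in self.values.dtypes):
            raise ParseError("matrix contains non-numeric columns")
        if self.scale == "beta":
            vals = self.values.to_numpy(dtype=float)
            present = ~np.isnan(vals)
            low, high = vals < 0.0, vals > 1.0
            salvage = (vals > -BETA_CLAMP_TOL) & (vals < 1.0 + BETA_CLAMP_TOL)
            bad = present & (low | high) & ~salvage
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ParseError(
                    f"beta value out of [0, 1] at feature {self.values.index[i]!r}, "
                    f"sample {self.values.columns[j]!r}: {vals[i, j]!r}"
                )
            if ((present & (low | high)) & salvage).any():
                self.values = self.values.clip(lower=0.0, upper=1.0)
            if np.isinf(vals).any():
                raise ParseError("beta matrix contains non-finite values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_ids(self) -> pd.Index:
        return self.values.columns[(self.group == "case").to_numpy()]

    @property
    def control_ids(self) -> pd.Index:
        return self.values.columns[(self.group == "control").to_numpy()]

    def subset_samples(self, sample_ids: Sequence[str]) -> "LabeledMatrix":
        """Restrict to the given samples (order preserved as given)."""
        gender = self.gender.loc[list(sample_ids)] if self.gender is not None else None
        return LabeledMatrix(
            values=self.values.loc[:, list(sample_ids)],
            scale=self.scale,
            group=self.group.loc[list(sample_ids)],
            gender=gender,
        )

    def require_two_groups(self, min_per_group: int = 1) -> None:
        for g in GROUPS:
            n = int((self.group == g).sum())
            if n < min_per_group:
                raise ConfigError(f"group {g!r} has {n} samples; need at least {min_per_group}")


@dataclass
class ProbeAnnotation:
    """Per-CpG annotation: position, gene/region assignments, enhancer flag.

    ``probes`` is indexed by probe_id with columns chr, position, enhancer,
    intergenic. ``assignments`` is the expanded long table with one row per
    (probe_id, gene, region) pair; a probe is intergenic exactly when it has
    no assignment rows.
    """

    probes: pd.DataFrame
    assignments: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.probes.index.has_duplicates:
            raise ParseError("duplicate probe identifiers in annotation")
        bad = set(self.assignments["region"]) - set(REGIONS)
        if bad:
            raise ParseError(f"unknown region labels: {sorted(bad)}")
        assigned = set(self.assignments["probe_id"])
        intergenic = set(self.probes.index[self.probes["intergenic"]])
        if assigned & intergenic:
            raise ParseError("probe flagged intergenic but carries gene assignments")
        orphan = assigned - set(self.probes.index)
        if orphan:
            raise ParseError(f"assignments reference unknown probes: {sorted(orphan)[:5]}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    @property
    def intergenic_ids(self) -> pd.Index:
        return self.probes.index[self.probes["intergenic"]]

    def enhancer_flags(self, probe_ids: Iterable[str]) -> pd.Series:
        return self.probes.loc[list(probe_ids), "enhancer"]


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - delegated parse failures
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample sidecar TSV (sample_id, group, optional gender)."""
    meta = _read_tsv(Path(path))
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ParseError(f"{path}: metadata needs columns sample_id and group")
    if meta["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def read_matrix(
    path: str | Path,
    scale: str,
    metadata: str | Path | pd.DataFrame,
) -> LabeledMatrix:
    """Read a features x samples TSV matrix plus its sample metadata.

    Beta matrices get the missingness policy applied: probes missing in more
    than 20% of samples are dropped (with a logged count); values outside
    [0, 1] by more than 1e-9 are rejected, smaller overshoots clamped.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.name not in (None, "ID"):
        logger.debug("matrix %s: first column header %r treated as feature IDs", path, raw.index.name)
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            bad_rows = raw.index[pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r}"
                + (f", row {bad_rows[0]!r}" if len(bad_rows) else "")
            )
    raw.index = raw.index.astype(str)
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    missing = [s for s in raw.columns if s not in metadata.index]
    if missing:
        raise ParseError(f"{path}: samples missing from metadata: {missing[:5]}")
    group = metadata["group"].astype(str)
    gender = metadata["gender"].astype(str) if "gender" in metadata.columns else None
    if scale == "beta":
        frac_missing = raw.isna().mean(axis=1)
        drop = frac_missing > MAX_MISSING_FRACTION
        if drop.any():
            logger.info(
                "%s: dropping %d probes missing in >%d%% of samples",
                path, int(drop.sum()), int(MAX_MISSING_FRACTION * 100),
            )
            raw = raw.loc[~drop]
    return LabeledMatrix(values=raw, scale=scale, group=group, gender=gender)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a manifest-style probe annotation TSV.

    Expected columns (manifest aliases in parentheses): probe_id (IlmnID),
    chr (CHR), position (MAPINFO), gene_names (UCSC_RefGene_Name),
    region_groups (UCSC_RefGene_Group), enhancer (Enhancer). gene_names and
    region_groups are parallel semicolon lists; duplicate (gene, region)
    pairs are deduplicated; an empty gene list marks the probe intergenic.
    """
    path = Path(path)
    raw = _read_tsv(path).rename(columns=_ANNOTATION_ALIASES)
    required = {"probe_id", "chr", "position", "gene_names", "region_groups", "enhancer"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing_cols)}")
    if raw["probe_id"].duplicated().any():
        dupes = raw.loc[raw["probe_id"].duplicated(), "probe_id"].tolist()
        raise ParseError(f"{path}: duplicate probe_id {dupes[:5]}")

    records: list[tuple[str, str, str]] = []
    intergenic: list[bool] = []
    for row in raw.itertuples(index=False):
        genes = [g for g in str(row.gene_names).split(";")] if pd.notna(row.gene_names) else []
        regions = [r for r in str(row.region_groups).split(";")] if pd.notna(row.region_groups) else []
        genes = [g.strip() for g in genes if g.strip()]
        regions = [r.strip() for r in regions if r.strip()]
        if len(genes) != len(regions):
            raise ParseError(
                f"{path}: probe {row.probe_id!r} has {len(genes)} gene names "
                f"but {len(regions)} region groups"
            )
        pairs = set()
        for gene, region in zip(genes, regions):
            if region not in _REGION_SYNONYMS:
                raise ParseError(f"{path}: probe {row.probe_id!r} has unknown region {region!r}")
            pairs.add((gene, _REGION_SYNONYMS[region]))
        intergenic.append(not pairs)
        records.extend((row.probe_id, g, r) for g, r in sorted(pairs))

    try:
        position = pd.to_numeric(raw["position"]).astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric probe position: {exc}") from exc
    enhancer = raw["enhancer"].fillna("").astype(str).str.upper().isin({"TRUE", "T", "1", "YES"})
    probes = pd.DataFrame(
        {
            "chr": raw["chr"].astype(str).to_numpy(),
            "position": position.to_numpy(),
            "enhancer": enhancer.to_numpy(),
            "intergenic": intergenic,
        },
        index=pd.Index(raw["probe_id"], name="probe_id"),
    )
    assignments = pd.DataFrame(records, columns=["probe_id", "gene", "region"])
    return ProbeAnnotation(probes=probes, assignments=assignments)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a features x samples matrix in the dialect ``read_matrix`` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.copy()
    out.index.name = "ID"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_series_matrix_values(path: str | Path) -> pd.DataFrame:
    """Extract the value table from a GEO series-matrix TSV.

    Only the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is parsed; all ``!`` header lines are
    ignored. Group labels must still be supplied via the metadata sidecar.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise ParseError(f"{path}: no series-matrix table block found") from exc
    from io import StringIO

    block = "\n".join(lines[start + 1 : end])
    table = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [c.strip('"') for c in table.columns]
    return table
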