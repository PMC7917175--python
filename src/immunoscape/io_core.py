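"""Readers, writers and preprocessing for the tabular formats the pipeline touches.

Expression matrices, clinical follow-up tables, MAF-lite mutation catalogs and
GMT gene-set collections are all plain TSV/GMT text.  Expression values enter
on FPKM scale and are filtered and transformed to log2(FPKM + 1) by
:func:`preprocess_expression` before any downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_FPKM = "raw_fpkm"
LOG2P1 = "log2p1"

DEFAULT_MISSING_TOKENS = ("", "NA")


class ParseError(ValueError):
    """A file violated the expected dialect; the message names the location."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with a scale tag.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  ``scale_tag`` is ``"raw_fpkm"`` for linear FPKM input or
    ``"log2p1"`` after log2(x+1) transformation.
    """

    values: pd.DataFrame
    scale_tag: str = LOG2P1

    def __post_init__(self) -> None:
        if self.scale_tag not in (RAW_FPKM, LOG2P1):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in ExpressionMatrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in ExpressionMatrix")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("non-finite values in ExpressionMatrix")
        if self.scale_tag == LOG2P1 and arr.size and arr.min() < 0:
            raise ValueError("log2p1 expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MutationCatalog:
    """Deduplicated per-sample somatic mutation records (MAF-lite).

    ``records`` has columns sample_id, gene_id, variant_class (plus optional
    position columns used only for deduplication).
    """

    records: pd.DataFrame
    altered_genome_fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "variant_class"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"mutation records need columns {sorted(required)}")
        if self.altered_genome_fraction is not None:
            f = self.altered_genome_fraction
            if ((f < 0) | (f > 1)).any():
                raise ValueError("altered_genome_fraction outside [0,1]")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())


@dataclass
class SignatureSet:
    """Named gene sets (GMT collection): name -> (description, ordered genes)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# readers


def _parse_numeric_table(path: Path, missing_ok: bool = False) -> pd.DataFrame:
    """Strict TSV parser: header row, first column = row ids, numeric body.

    Raises :class:`ParseError` naming the offending cell for ragged rows or
    non-numeric entries.  Pandas' lenient coercions would silently hide both.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")[1:]
        ncol = len(cols)
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol + 1:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {ncol + 1})"
                )
            row_ids.append(fields[0])
            vals = []
            for j, tok in enumerate(fields[1:]):
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {tok!r} "
                        f"in row {fields[0]!r}, column {cols[j]!r}"
                    ) from None
            rows.append(vals)
    return pd.DataFrame(rows, index=row_ids, columns=cols, dtype=float)


def read_expression(
    path: str | Path,
    orientation: str = "genes_by_samples",
    scale_tag: str = RAW_FPKM,
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    ``orientation`` is ``"genes_by_samples"`` (rows = genes) or
    ``"samples_by_genes"`` (transposed on read).  Duplicate gene ids are
    collapsed by keeping the row with the highest mean (logged).
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _parse_numeric_table(Path(path))
    if orientation == "samples_by_genes":
        df = df.T
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        keep = np.zeros(len(df), dtype=bool)
        order = np.arange(len(df))
        for gene, grp in pd.Series(order, index=df.index).groupby(level=0, sort=False):
            pos = grp.to_numpy()
            best = pos[np.argmax(means.to_numpy()[pos])]
            keep[best] = True
        n_dropped = (~keep).sum()
        logger.info("collapsed %d duplicate gene rows by highest mean", n_dropped)
        df = df.iloc[keep]
    return ExpressionMatrix(values=df, scale_tag=scale_tag)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write genes-by-samples TSV at full float precision (round-trip safe)."""
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | Path) -> SignatureSet:
    """Read a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``.

    Within-set duplicate genes are removed preserving first occurrence;
    duplicate set names or lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            desc[name] = description
    return SignatureSet(sets=sets, descriptions=desc)


def write_gmt(sig: SignatureSet, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in sig:
            d = sig.descriptions.get(name, "na")
            fh.write("\t".join([name, d, *genes]) + "\n")


CLINICAL_COLUMNS = ("os_time", "os_event", "rfs_time", "rfs_event", "stage", "grade")


def read_clinical(
    path: str | Path,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> pd.DataFrame:
    """Read a clinical TSV into a typed table indexed by sample_id.

    Columns: os_time (days), os_event {0,1}, rfs_time, rfs_event, stage,
    grade (ordinal 1..4); the last four may be missing.  Rows lacking os_time
    or os_event are dropped with a logged count.  Duplicate sample ids and
    event flags outside {0,1} are errors.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=list(missing_tokens)
    )
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    out = pd.DataFrame(index=pd.Index(df["sample_id"], name="sample_id"))
    for col in CLINICAL_COLUMNS:
        if col in df.columns:
            out[col] = pd.to_numeric(df[col].to_numpy(), errors="raise")
        else:
            out[col] = np.nan
    for col in ("os_event", "rfs_event"):
        vals = out[col].dropna()
        if not vals.isin([0, 1]).all():
            bad = vals[~vals.isin([0, 1])].iloc[0]
            raise ParseError(f"{path}: {col} value {bad!r} outside {{0,1}}")
    for col in ("os_time", "rfs_time"):
        vals = out[col].dropna()
        if (vals < 0).any():
            raise ParseError(f"{path}: negative {col}")
    complete = out["os_time"].notna() & out["os_event"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%d row(s) dropped for missing OS time/event", n_dropped)
    return out.loc[complete]


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def read_mutations(
    path: str | Path,
    exclude_classes: Iterable[str] | None = ("Silent",),
) -> MutationCatalog:
    """Read a MAF-lite TSV (sample_id, gene_id, variant_class [, position...]).

    Duplicate (sample, gene, position-surrogate) records are removed; variant
    classes in ``exclude_classes`` (default: Silent) are dropped.  Empty or
    header-only files and unknown column layouts are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {"Tumor_Sample_Barcode": "sample_id", "Hugo_Symbol": "gene_id",
              "Variant_Classification": "variant_class", "gene": "gene_id"}
    df = df.rename(columns=rename)
    required = {"sample_id", "gene_id", "variant_class"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: unknown column layout {list(df.columns)}; need {sorted(required)}"
        )
    if df.empty:
        raise ParseError(f"{path}: no mutation records")
    if exclude_classes:
        df = df[~df["variant_class"].isin(set(exclude_classes))]
    dedup_keys = ["sample_id", "gene_id", "variant_class"]
    for pos_col in ("chrom", "pos", "Start_Position"):
        if pos_col in df.columns:
            dedup_keys.append(pos_col)
    df = df.drop_duplicates(subset=dedup_keys).reset_index(drop=True)
    return MutationCatalog(records=df)


def write_mutations(cat: MutationCatalog, path: str | Path) -> None:
    cat.records.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a samples-by-columns numeric score table (infiltration, purity...)."""
    return _parse_numeric_table(Path(path))


def write_score_table(df: pd.DataFrame, path: str | Path, index_name: str = "sample_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_expression(
    m: ExpressionMatrix, zero_fraction_max: float = 0.5
) -> ExpressionMatrix:
    """Filter near-silent genes and move to log2(FPKM + 1) scale.

    Genes with a zero FPKM value in strictly more than ``zero_fraction_max``
    of samples are removed (gene order otherwise preserved), then values are
    transformed to log2(x + 1).  Input must be on raw FPKM scale.
    """
    if m.scale_tag != RAW_FPKM:
        raise ValueError("preprocess_expression expects raw_fpkm input")
    if not 0 < zero_fraction_max <= 1:
        raise ValueError("zero_fraction_max must be in (0, 1]")
    vals = m.values
    zero_frac = (vals == 0).mean(axis=1)
    keep = zero_frac <= zero_fraction_max
    if not keep.any():
        raise ValueError("empty matrix after filtering")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d gene(s) with zero FPKM in > %.0f%% of samples",
                    n_removed, 100 * zero_fraction_max)
    out = np.log2(vals.loc[keep] + 1.0)
    return ExpressionMatrix(values=out, scale_tag=LOG2P1)
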