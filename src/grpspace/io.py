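"""Readers and writers for the files the pipeline touches.

Expression matrices travel as TSV (genes in rows, header row of sample
IDs), gene annotations as 4-column BED-like TSV (chrom, start, end,
gene_id; 0-based half-open), and mutual-information matrices as an HDF5
container (gene-ID vector + dense float64 matrix) with a gzip-TSV
fallback. All writers and readers are exact inverses on valid inputs.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromosomes import chrom_sort_key, normalize_chromosome
from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values for one condition.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (rows).
    sample_ids
        Ordered unique sample identifiers (columns).
    values
        ``(n_genes, n_samples)`` float64 array, non-negative, no NaN.
    condition
        Free-text condition label (typically ``"tumor"`` or ``"control"``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ContractError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ContractError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ContractError("duplicate gene IDs in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ContractError("duplicate sample IDs in expression matrix")
        if not np.isfinite(self.values).all():
            raise ContractError("expression values contain NaN or infinity")
        if (self.values < 0).any():
            raise ContractError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneAnnotation:
    """Mapping of genes to chromosomes (and optional bp coordinates).

    Backed by a BED-like table with columns ``chrom``, ``start``, ``end``,
    ``gene_id`` (0-based half-open coordinates). Chromosome labels live in
    the canonical universe 1..22, X.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "gene_id"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ContractError(f"annotation table missing columns: {missing}")
        self.table = self.table[required].reset_index(drop=True)
        ids = self.table["gene_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ContractError(f"duplicate gene ID in annotation: {dup!r}")
        bad = [c for c in self.table["chrom"].unique() if normalize_chromosome(str(c)) != c]
        if bad:
            raise ContractError(f"non-canonical chromosome labels in annotation: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def chromosome_of(self) -> dict[str, str]:
        """gene_id -> chromosome label."""
        return dict(zip(self.table["gene_id"], self.table["chrom"]))

    def start_of(self) -> dict[str, int]:
        """gene_id -> start coordinate (bp)."""
        return dict(zip(self.table["gene_id"], self.table["start"].astype(int)))

    def chromosomes(self) -> list[str]:
        """Chromosome labels present, in canonical order."""
        return sorted(set(self.table["chrom"]), key=chrom_sort_key)

    def digest(self) -> str:
        """Stable checksum of the annotation content (order-insensitive)."""
        canon = self.table.sort_values("gene_id").to_csv(sep="\t", index=False)
        return hashlib.sha256(canon.encode()).hexdigest()


def read_expression(path: str | Path, condition_label: str = "") -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    The first row is the sample-ID header, the first column holds gene
    IDs. Negative or non-numeric entries and duplicate gene IDs are
    format errors.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, header=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:  # ragged rows carry the line number
        raise FormatError(f"{path}: malformed expression TSV: {exc}") from exc
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna()
    if bad_mask.any().any():
        gene = numeric.index[bad_mask.any(axis=1)][0]
        raise FormatError(f"{path}: non-numeric value in gene {gene!r}")
    if (numeric.values < 0).any():
        gene = numeric.index[(numeric.values < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative value in gene {gene!r}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=[str(s) for s in numeric.columns],
        values=numeric.values.astype(np.float64),
        condition=condition_label,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    # %.17g keeps the full float64 precision so the round trip is exact
    expr.to_frame().to_csv(Path(path), sep="\t", index_label="gene_id", float_format="%.17g")


def read_annotation(path: str | Path, strict: bool = False) -> GeneAnnotation:
    """Read a BED-like annotation TSV (chrom, start, end, gene_id).

    Labels are normalized (``chr`` prefix stripped, ``x`` -> ``X``). Genes
    on chromosomes outside 1..22, X (Y, MT, "23", ...) are dropped with a
    logged count by default; with ``strict=True`` they raise instead.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
        comment="#",
    )
    if frame[["start", "end", "gene_id"]].isna().any().any():
        raise FormatError(f"{path}: annotation rows must have 4 columns")
    normalized = frame["chrom"].map(lambda c: normalize_chromosome(str(c)))
    dropped = frame.loc[normalized.isna(), "chrom"].tolist()
    if dropped:
        if strict:
            raise FormatError(f"{path}: unknown chromosome labels: {sorted(set(dropped))}")
        logger.warning(
            "%s: dropped %d gene(s) on non-canonical chromosomes %s",
            path, len(dropped), sorted(set(map(str, dropped))),
        )
    keep = frame[normalized.notna()].copy()
    keep["chrom"] = normalized[normalized.notna()]
    keep["start"] = keep["start"].astype(int)
    keep["end"] = keep["end"].astype(int)
    return GeneAnnotation(keep[["chrom", "start", "end", "gene_id"]])


def write_annotation(annot: GeneAnnotation, path: str | Path) -> None:
    annot.table.to_csv(Path(path), sep="\t", index=False, header=False)


def write_mi_matrix(mi, path: str | Path) -> None:
    """Persist an MIMatrix losslessly.

    ``.h5``/``.hdf5`` suffixes select the HDF5 container (gene-ID vector
    plus dense matrix); ``.tsv.gz`` selects the gzip-TSV fallback. The
    matrix must be symmetric with a zero diagonal.
    """
    from .mi import MIMatrix  # local import to avoid a module cycle

    assert isinstance(mi, MIMatrix)
    path = Path(path)
    _check_mi_values(mi.values)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as handle:
            handle.create_dataset("gene_ids", data=np.array(mi.gene_ids, dtype="S"))
            handle.create_dataset("mi", data=mi.values, dtype="f8")
            for key, value in mi.estimator_meta.items():
                handle.attrs[key] = value
    elif path.name.endswith(".tsv.gz"):
        with gzip.open(path, "wt") as handle:
            handle.write("\t".join(["gene_id"] + list(mi.gene_ids)) + "\n")
            for gid, row in zip(mi.gene_ids, mi.values):
                cells = "\t".join(np.format_float_scientific(v, precision=17) for v in row)
                handle.write(f"{gid}\t{cells}\n")
    else:
        raise FormatError(f"unsupported MI matrix format: {path.name}")


def read_mi_matrix(path: str | Path):
    """Read an MIMatrix written by :func:`write_mi_matrix`."""
    from .mi import MIMatrix

    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as handle:
            gene_ids = [g.decode() for g in handle["gene_ids"][()]]
            values = handle["mi"][()]
            meta = dict(handle.attrs)
    elif path.name.endswith(".tsv.gz"):
        with gzip.open(path, "rt") as handle:
            header = handle.readline().rstrip("\n").split("\t")[1:]
            gene_ids = header
            rows = []
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
            values = np.array(rows, dtype=np.float64)
        meta = {}
    else:
        raise FormatError(f"unsupported MI matrix format: {path.name}")
    _check_mi_values(values)
    return MIMatrix(gene_ids=gene_ids, values=values, estimator_meta=meta)


def _check_mi_values(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ContractError("MI matrix must be square")
    if not np.array_equal(values, values.T):
        raise ContractError("MI matrix must be symmetric")
    if np.any(np.diagonal(values) != 0.0):
        raise ContractError("MI matrix diagonal must be exactly zero")
    if (values < 0).any():
        raise ContractError("MI values must be non-negative")
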