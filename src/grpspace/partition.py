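"""Partition of an MI matrix into chromosome-pair sub-regulatory programs.

The global regulatory program over N genes decomposes by chromosome
membership: for chromosomes k, l the sub-program G^{k,l} holds the MI
values of all gene pairs with one gene on k and the other on l. The
diagonal blocks (k == l) are the cis programs, off-diagonal blocks the
trans programs; every unordered gene pair lands in exactly one block,
so block pair counts sum to N(N-1)/2. With all 23 canonical chromosomes
populated there are 23 cis + 253 trans = 276 sub-programs.

The partition depends only on the gene set and annotation, never on MI
values; gene pairs are enumerated in lexicographic gene-ID order so two
collections built from the same annotation align element-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chromosomes import chrom_sort_key
from .errors import ContractError
from .io import GeneAnnotation
from .mi import MIMatrix

logger = logging.getLogger(__name__)

Key = tuple[str, str]


@dataclass
class SubGRP:
    """MI values of one chromosome-pair sub-regulatory program."""

    key: Key
    kind: str  # "cis" | "trans"
    values: np.ndarray
    gene_pair_index: list[tuple[str, str]]

    @property
    def n_pairs(self) -> int:
        return len(self.values)


@dataclass
class GRPCollection:
    """All sub-regulatory programs of one condition's regulatory program."""

    condition: str
    sub_grps: dict[Key, SubGRP]
    annotation_digest: str
    gene_ids: list[str] = field(default_factory=list)

    def total_pairs(self) -> int:
        return sum(s.n_pairs for s in self.sub_grps.values())

    def keys_of_kind(self, kind: str) -> list[Key]:
        return [k for k, s in self.sub_grps.items() if s.kind == kind]


def partition_grp(mi: MIMatrix, annot: GeneAnnotation, strict: bool = False) -> GRPCollection:
    """Split *mi* into cis/trans sub-programs keyed by chromosome pair.

    Genes present in the matrix but absent from the annotation are
    dropped with a logged count (error in strict mode). Keys are
    canonical unordered pairs (k <= l in the order 1..22, X); trans
    programs pool both directions.
    """
    chrom_of = annot.chromosome_of()
    condition = str(mi.estimator_meta.get("condition", ""))
    pos = {g: i for i, g in enumerate(mi.gene_ids)}
    annotated = [g for g in mi.gene_ids if g in chrom_of]
    n_dropped = len(mi.gene_ids) - len(annotated)
    if n_dropped:
        if strict:
            missing = [g for g in mi.gene_ids if g not in chrom_of]
            raise ContractError(f"genes without annotation: {missing[:5]}...")
        logger.warning("dropped %d gene(s) without annotation", n_dropped)
    if not annotated:
        raise ContractError("no annotated genes in MI matrix")

    genes_by_chrom: dict[str, list[str]] = {}
    for g in sorted(annotated):  # lexicographic canonical order
        genes_by_chrom.setdefault(chrom_of[g], []).append(g)
    chroms = sorted(genes_by_chrom, key=chrom_sort_key)

    values = mi.values
    sub_grps: dict[Key, SubGRP] = {}
    for a, k in enumerate(chroms):
        gk = genes_by_chrom[k]
        ik = np.array([pos[g] for g in gk])
        # cis block: unordered pairs within chromosome k
        pairs = [(gk[i], gk[j]) for i in range(len(gk)) for j in range(i + 1, len(gk))]
        if pairs:
            rows, cols = np.triu_indices(len(gk), k=1)
            vals = values[ik[rows], ik[cols]]
        else:
            vals = np.empty(0)
        sub_grps[(k, k)] = SubGRP((k, k), "cis", vals, pairs)
        for l in chroms[a + 1:]:
            gl = genes_by_chrom[l]
            il = np.array([pos[g] for g in gl])
            pairs = [(gi, gj) for gi in gk for gj in gl]
            vals = values[np.repeat(ik, len(il)), np.tile(il, len(ik))]
            sub_grps[(k, l)] = SubGRP((k, l), "trans", vals, pairs)

    collection = GRPCollection(
        condition=condition,
        sub_grps=sub_grps,
        annotation_digest=annot.digest(),
        gene_ids=annotated,
    )
    n = len(annotated)
    if collection.total_pairs() != n * (n - 1) // 2:
        raise ContractError(
            f"pair conservation violated: {collection.total_pairs()} != "
            f"{n * (n - 1) // 2}"
        )
    return collection


def summary_frame(collection: GRPCollection) -> "pd.DataFrame":
    """Per-sub-program summary (key, kind, pair count, mean/median MI)."""
    import pandas as pd

    rows = []
    for key in sorted(
        collection.sub_grps,
        key=lambda k: (chrom_sort_key(k[0]), chrom_sort_key(k[1])),
    ):
        sub = collection.sub_grps[key]
        rows.append(
            {
                "key_k": key[0],
                "key_l": key[1],
                "kind": sub.kind,
                "n_pairs": sub.n_pairs,
                "mean_mi": float(np.mean(sub.values)) if sub.n_pairs else np.nan,
                "median_mi": float(np.median(sub.values)) if sub.n_pairs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def align_sub_grps(a: GRPCollection, b: GRPCollection) -> tuple[GRPCollection, GRPCollection]:
    """Verify two collections are element-wise comparable and return them.

    Both must derive from the same annotation and gene set; for every
    key the gene-pair enumeration must be identical (guaranteed by the
    canonical ordering in :func:`partition_grp`, checked here).
    """
    if a.annotation_digest != b.annotation_digest:
        raise ContractError("collections built from different annotations")
    if set(a.gene_ids) != set(b.gene_ids):
        only_a = sorted(set(a.gene_ids) - set(b.gene_ids))
        only_b = sorted(set(b.gene_ids) - set(a.gene_ids))
        raise ContractError(
            f"gene sets differ: only in first={only_a[:5]}, only in second={only_b[:5]}"
        )
    if set(a.sub_grps) != set(b.sub_grps):
        raise ContractError("sub-program keys differ between collections")
    for key in a.sub_grps:
        if a.sub_grps[key].gene_pair_index != b.sub_grps[key].gene_pair_index:
            raise ContractError(f"gene-pair order mismatch in sub-program {key}")
    return a, b
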