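"""Canonical chromosome label universe and ordering.

The analysis is restricted to the human autosomes plus X (labels
``"1"``..``"22"``, ``"X"``); Y and organellar contigs are outside the
label universe. Canonical order is numeric for autosomes with X last.
"""

from __future__ import annotations

from .errors import FormatError

#: Allowed chromosome labels, in canonical order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

_CHROM_RANK = {label: rank for rank, label in enumerate(CHROMOSOMES)}


def chrom_sort_key(label: str) -> int:
    """Rank of *label* in the canonical order 1..22, X."""
    try:
        return _CHROM_RANK[label]
    except KeyError:
        raise FormatError(f"unknown chromosome label: {label!r}") from None


def canonical_pair(k: str, l: str) -> tuple[str, str]:
    """Unordered chromosome pair in canonical (k <= l) order."""
    if chrom_sort_key(k) <= chrom_sort_key(l):
        return (k, l)
    return (l, k)


def normalize_chromosome(raw: str) -> str | None:
    """Normalize a raw chromosome label, or return None if outside 1..22,X.

    Strips a ``chr`` prefix and upper-cases ``x``. ``"23"`` is not a valid
    alias for X and is rejected (returns None) like Y or MT.
    """
    label = raw.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.lower() == "x":
        label = "X"
    return label if label in _CHROM_RANK else None
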