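"""Differential-network indicators: ΔG, gain-loss score, gain-loss ratio.

For every chromosome pair the element-wise MI difference
``delta = tumor - control`` summarizes how that sub-regulatory program
changed between phenotypes. Two aggregates are reported per pair:

* GLS (gain-loss score): (number of gains - number of losses) / total
  pair count, in [-1, 1]. Exact zero deltas are ties: they count in the
  denominator only.
* GLR (gain-loss ratio): mean MI gain / |mean MI loss|; > 1 when gains
  outweigh losses in magnitude. Degenerate programs map to 0 (no
  gains), +inf (no losses), or an error (all ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chromosomes import chrom_sort_key
from .errors import ContractError, UndefinedIndicatorError
from .partition import GRPCollection, Key, align_sub_grps


@dataclass
class DeltaGRP:
    """Aligned MI differences (tumor - control) for one chromosome pair."""

    key: Key
    deltas: np.ndarray
    kind: str = ""


@dataclass
class ChangeIndicators:
    """GLS/GLR summary row for one chromosome-pair sub-program."""

    key: Key
    kind: str
    n_pairs: int
    n_gains: int
    n_losses: int
    n_ties: int
    gls: float
    glr: float


def delta_grp(tumor: GRPCollection, control: GRPCollection) -> dict[Key, DeltaGRP]:
    """Element-wise MI differences per chromosome pair (tumor - control)."""
    tumor, control = align_sub_grps(tumor, control)
    return {
        key: DeltaGRP(
            key=key,
            deltas=tumor.sub_grps[key].values - control.sub_grps[key].values,
            kind=tumor.sub_grps[key].kind,
        )
        for key in tumor.sub_grps
    }


def gain_loss_score(d: DeltaGRP) -> float:
    """(gains - losses) / total pairs; exact-zero deltas are ties."""
    n = len(d.deltas)
    if n == 0:
        raise UndefinedIndicatorError(f"empty sub-program {d.key}")
    n_gains = int(np.sum(d.deltas > 0))
    n_losses = int(np.sum(d.deltas < 0))
    return (n_gains - n_losses) / n


def gain_loss_ratio(d: DeltaGRP) -> float:
    """mean(gains) / |mean(losses)|; 0 without gains, +inf without losses."""
    if len(d.deltas) == 0:
        raise UndefinedIndicatorError(f"empty sub-program {d.key}")
    gains = d.deltas[d.deltas > 0]
    losses = d.deltas[d.deltas < 0]
    if gains.size == 0 and losses.size == 0:
        raise UndefinedIndicatorError(f"all deltas are ties in sub-program {d.key}")
    if losses.size == 0:
        return math.inf
    if gains.size == 0:
        return 0.0
    return float(np.mean(gains) / abs(np.mean(losses)))


def indicator_table(deltas: dict[Key, DeltaGRP]) -> list[ChangeIndicators]:
    """One GLS/GLR row per chromosome pair, in canonical key order."""
    if not deltas:
        raise ContractError("no sub-programs to summarize")
    rows = []
    for key in sorted(deltas, key=lambda k: (chrom_sort_key(k[0]), chrom_sort_key(k[1]))):
        d = deltas[key]
        n = len(d.deltas)
        if n == 0:
            continue  # empty sub-program: indicators undefined, skipped
        n_gains = int(np.sum(d.deltas > 0))
        n_losses = int(np.sum(d.deltas < 0))
        try:
            glr = gain_loss_ratio(d)
        except UndefinedIndicatorError:
            glr = math.nan  # all ties: ratio of means over two empty sets
        rows.append(
            ChangeIndicators(
                key=key,
                kind=d.kind or ("cis" if key[0] == key[1] else "trans"),
                n_pairs=n,
                n_gains=n_gains,
                n_losses=n_losses,
                n_ties=n - n_gains - n_losses,
                gls=gain_loss_score(d),
                glr=glr,
            )
        )
    return rows


def indicators_to_frame(rows: list[ChangeIndicators]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "key_k": [r.key[0] for r in rows],
            "key_l": [r.key[1] for r in rows],
            "kind": [r.kind for r in rows],
            "n_pairs": [r.n_pairs for r in rows],
            "n_gains": [r.n_gains for r in rows],
            "n_losses": [r.n_losses for r in rows],
            "n_ties": [r.n_ties for r in rows],
            "gls": [r.gls for r in rows],
            "glr": [r.glr for r in rows],
        }
    )


def write_indicator_table(rows: list[ChangeIndicators], path: str | Path) -> None:
    """TSV export; an infinite GLR serializes as the string ``inf``."""
    indicators_to_frame(rows).to_csv(Path(path), sep="\t", index=False)
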