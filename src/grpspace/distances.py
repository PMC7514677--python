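"""Distribution distances between sub-regulatory programs.

Two comparisons drive the analysis:

* tumor-vs-control, per chromosome pair: the two-sample
  Kolmogorov–Smirnov statistic ``sup_x |F_a(x) - F_b(x)|`` between the
  MI value samples of the same sub-program in the two conditions;
* cis-vs-trans, within one condition: for each anchor chromosome k the
  distance between the cis program G^{k,k} and every trans program
  G^{k,l}, either as a KS statistic on raw MI values or as the
  Hellinger distance ``H = sqrt(1/2 * sum (sqrt(p_i) - sqrt(q_i))^2)``
  between histogram densities on a shared support.

The Hellinger metric defaults to the standard square-root form; a
half-squared-Euclidean variant between the same densities is available
as ``metric="euclidean_sq"`` for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .chromosomes import canonical_pair, chrom_sort_key
from .errors import ContractError
from .partition import GRPCollection, Key, align_sub_grps

logger = logging.getLogger(__name__)


@dataclass
class HistogramPDF:
    """Discrete density on a shared equal-width binning."""

    bin_edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if len(self.masses) != len(self.bin_edges) - 1:
            raise ContractError("len(masses) must equal len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ContractError("bin_edges must be strictly increasing")
        if (self.masses < 0).any() or abs(self.masses.sum() - 1.0) > 1e-12:
            raise ContractError("masses must be non-negative and sum to 1")


@dataclass
class DistanceRecord:
    """One distance between two sub-programs (possibly across conditions)."""

    program_a: tuple[Key, str]  # (chromosome pair, condition)
    program_b: tuple[Key, str]
    metric: str
    value: float


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sample KS statistic: sup over pooled points of |ECDF diff|."""
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ContractError("KS statistic requires non-empty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_p_value(a: np.ndarray, b: np.ndarray) -> float:
    """Asymptotic two-sample KS p-value (Kolmogorov distribution).

    Uses Stephens' finite-sample argument correction
    ``(en + 0.12 + 0.11/en) * D`` with ``en = sqrt(nm/(n+m))``, which
    keeps the null p-value close to uniform down to moderate sample
    sizes where the raw asymptotic form is visibly biased.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ContractError("KS test requires non-empty samples")
    d = ks_statistic(a, b)
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    return float(np.clip(special.kolmogorov((en + 0.12 + 0.11 / en) * d), 0.0, 1.0))


def neglog_transform(d: float, pooled_n: int | None = None) -> float:
    """-ln(d) for a distance d > 0; d == 0 is capped using the pooled size.

    A zero distance maps to ``-ln(1 / (pooled_n + 1))`` (logged), the
    resolution limit of an ECDF comparison at that sample size.
    """
    if d < 0:
        raise ContractError("distance must be non-negative")
    if d == 0:
        if pooled_n is None:
            raise ContractError("neglog_transform(0) requires pooled_n")
        eps = 1.0 / (pooled_n + 1)
        logger.warning("zero distance capped at -ln(%g)", eps)
        return -math.log(eps)
    return -math.log(d)


def estimate_pdf(
    values: np.ndarray, n_bins: int, shared_range: tuple[float, float]
) -> HistogramPDF:
    """Equal-width histogram density of *values* on *shared_range*."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ContractError("cannot estimate a density from no values")
    lo, hi = shared_range
    if not hi > lo:
        raise ContractError(f"zero-width range: {shared_range}")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    total = counts.sum()
    if total == 0:
        raise ContractError("no values fall inside shared_range")
    return HistogramPDF(bin_edges=edges, masses=counts / total)


def hellinger_distance(p: HistogramPDF, q: HistogramPDF, form: str = "standard") -> float:
    """Distance between two histogram densities on identical bins.

    ``form="standard"`` is the Hellinger metric
    ``sqrt(1/2 * sum (sqrt p - sqrt q)^2)`` in [0, 1];
    ``form="euclidean_sq"`` is the half-squared-Euclidean variant
    ``1/2 * sum (p - q)^2``.
    """
    if not np.array_equal(p.bin_edges, q.bin_edges):
        raise ContractError("Hellinger distance requires identical bin edges")
    if form == "standard":
        h = math.sqrt(0.5 * np.sum((np.sqrt(p.masses) - np.sqrt(q.masses)) ** 2))
        return min(h, 1.0)
    if form == "euclidean_sq":
        return float(0.5 * np.sum((p.masses - q.masses) ** 2))
    raise ContractError(f"unknown Hellinger form: {form!r}")


def condition_comparison(
    tumor: GRPCollection, control: GRPCollection
) -> list[DistanceRecord]:
    """KS statistic tumor-vs-control for every chromosome-pair program."""
    tumor, control = align_sub_grps(tumor, control)
    records = []
    for key in sorted(
        tumor.sub_grps, key=lambda k: (chrom_sort_key(k[0]), chrom_sort_key(k[1]))
    ):
        sa, sb = tumor.sub_grps[key], control.sub_grps[key]
        if sa.n_pairs == 0:
            logger.warning("sub-program %s empty; skipped", key)
            continue
        records.append(
            DistanceRecord(
                program_a=(key, tumor.condition or "tumor"),
                program_b=(key, control.condition or "control"),
                metric="ks",
                value=ks_statistic(sa.values, sb.values),
            )
        )
    return records


def cis_trans_comparison(
    grps: GRPCollection, metric: str = "ks", n_bins_pdf: int = 100
) -> list[DistanceRecord]:
    """Anchored cis-vs-trans distances within one condition.

    For every ordered chromosome pair (k, l), k != l, compares the cis
    program G^{k,k} with the trans program G^{k,l}: with all 23
    chromosomes populated this yields 506 directed records. Anchors
    whose cis program is empty (< 2 genes on the chromosome) are
    skipped with a warning. Hellinger densities share one equal-width
    support spanning all sub-program values of the collection.
    """
    if metric not in {"ks", "hellinger", "hellinger_euclidean_sq"}:
        raise ContractError(f"unknown metric: {metric!r}")
    chroms = sorted({k for key in grps.sub_grps for k in key}, key=chrom_sort_key)
    condition = grps.condition or ""

    shared_range = None
    pdf_cache: dict[Key, HistogramPDF] = {}
    if metric.startswith("hellinger"):
        pooled = [s.values for s in grps.sub_grps.values() if s.n_pairs > 0]
        lo = min(v.min() for v in pooled)
        hi = max(v.max() for v in pooled)
        if hi == lo:  # all MI values identical: widen degenerate support
            hi = lo + 1e-9
        shared_range = (float(lo), float(hi))

    def pdf_of(key: Key) -> HistogramPDF:
        if key not in pdf_cache:
            pdf_cache[key] = estimate_pdf(
                grps.sub_grps[key].values, n_bins_pdf, shared_range
            )
        return pdf_cache[key]

    records = []
    for k in chroms:
        cis_key = (k, k)
        if cis_key not in grps.sub_grps or grps.sub_grps[cis_key].n_pairs == 0:
            logger.warning("anchor %s has an empty cis program; skipped", k)
            continue
        for l in chroms:
            if l == k:
                continue
            trans_key = canonical_pair(k, l)
            sub = grps.sub_grps.get(trans_key)
            if sub is None or sub.n_pairs == 0:
                logger.warning("trans program %s empty; skipped", trans_key)
                continue
            if metric == "ks":
                value = ks_statistic(grps.sub_grps[cis_key].values, sub.values)
            else:
                form = "standard" if metric == "hellinger" else "euclidean_sq"
                value = hellinger_distance(pdf_of(cis_key), pdf_of(trans_key), form)
            records.append(
                DistanceRecord(
                    program_a=(cis_key, condition),
                    program_b=((k, l), condition),
                    metric=metric,
                    value=value,
                )
            )
    return records


def records_to_frame(records: list[DistanceRecord]) -> pd.DataFrame:
    """Flat table of distance records (anchor/other keys, metric, value)."""
    rows = []
    for r in records:
        (ka, la), cond_a = r.program_a
        (kb, lb), cond_b = r.program_b
        rows.append(
            {
                "a_k": ka, "a_l": la, "a_condition": cond_a,
                "b_k": kb, "b_l": lb, "b_condition": cond_b,
                "metric": r.metric,
                "value": r.value,
                "neglog_value": neglog_transform(r.value) if r.value > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_distance_table(records: list[DistanceRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(Path(path), sep="\t", index=False)


def distance_matrix_frame(records: list[DistanceRecord]) -> pd.DataFrame:
    """Anchor x other matrix of distance values (heatmap-ready export)."""
    frame = records_to_frame(records)
    return frame.pivot_table(
        index="a_k", columns="b_l", values="value", aggfunc="first", sort=False
    )
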