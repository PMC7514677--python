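"""Pairwise mutual-information estimation and MI-matrix assembly.

The gene regulatory program (GRP) of a phenotype is represented here as
the matrix of pairwise mutual information values

    I(X_i, X_j) = sum_xy P(x, y) * ln[ P(x, y) / (P(x) P(y)) ]

between gene expression profiles, with self-information removed (zero
diagonal). The default estimator discretizes each profile into
``ceil(n_samples ** (1/3))`` equal-frequency bins, computes the plug-in
MI of the joint histogram in nats, and applies the Miller–Madow bias
correction; negative corrected estimates are clamped to zero. The
cube-root rule keeps the joint histogram well populated (``B**2 << n``)
so the Miller–Madow-corrected estimate tracks the Gaussian closed form
within a few percent, whereas square-root-style rules leave ~1 sample
per joint cell and a bias that dwarfs weak dependencies.
Equal-frequency binning acts on ranks, so the estimate is exactly
invariant under strictly increasing transforms of either profile (a
decreasing transform reverses the bin boundaries, which only matters
when the sample size is not a multiple of the bin count).

The blocked matrix assembly evaluates every pair with exactly the same
floating-point operations as :func:`estimate_mi`, so results are
bit-identical for any worker count or chunking.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from scipy.stats import rankdata

from .errors import ContractError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_METHODS = ("equal_frequency_bins", "equal_width_bins")
_CORRECTIONS = ("none", "miller_madow")


@dataclass
class EstimatorConfig:
    """Discretization and bias-correction choices for the MI estimator.

    ``n_bins`` may be a positive integer or a rule string:
    ``"cbrt_n"`` (default, ``ceil(n_samples ** (1/3))``) or ``"sqrt_n"``
    (``ceil(sqrt(n_samples))``, only advisable for small n). All
    estimates are in natural log units (nats).
    """

    method: str = "equal_frequency_bins"
    n_bins: int | str = "cbrt_n"
    bias_correction: str = "miller_madow"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ContractError(f"unknown binning method: {self.method!r}")
        if self.bias_correction not in _CORRECTIONS:
            raise ContractError(f"unknown bias correction: {self.bias_correction!r}")
        if isinstance(self.n_bins, str):
            if self.n_bins not in {"cbrt_n", "sqrt_n"}:
                raise ContractError(f"unknown n_bins rule: {self.n_bins!r}")
        elif self.n_bins < 2:
            raise ContractError("n_bins must be >= 2")

    def resolve_bins(self, n_samples: int) -> int:
        if self.n_bins == "cbrt_n":
            bins = int(np.ceil(np.cbrt(n_samples)))
        elif self.n_bins == "sqrt_n":
            bins = int(np.ceil(np.sqrt(n_samples)))
        else:
            bins = int(self.n_bins)
        if bins < 2:
            raise ContractError("resolved n_bins must be >= 2")
        if bins > n_samples:
            raise ContractError(
                f"n_bins={bins} exceeds n_samples={n_samples}"
            )
        return bins


@dataclass
class MIMatrix:
    """Symmetric off-diagonal mutual-information matrix over genes."""

    gene_ids: list[str]
    values: np.ndarray
    estimator_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ContractError(
                f"MI matrix shape {self.values.shape} does not match {n} genes"
            )
        if len(set(self.gene_ids)) != n:
            raise ContractError("duplicate gene IDs in MI matrix")
        if not np.array_equal(self.values, self.values.T):
            raise ContractError("MI matrix must be symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ContractError("MI matrix diagonal must be exactly zero")
        if (self.values < 0).any():
            raise ContractError("MI values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def bin_codes(x: np.ndarray, n_bins: int, method: str = "equal_frequency_bins") -> np.ndarray:
    """Discretize a sample vector into integer bin codes in ``[0, n_bins)``.

    Equal-frequency binning assigns ``code = ceil(rank * B / n) - 1`` on
    average ranks, so tied values always share a bin and a constant
    vector collapses into a single bin (zero entropy).
    """
    x = np.asarray(x, dtype=np.float64)
    if method == "equal_frequency_bins":
        ranks = rankdata(x, method="average")
        codes = np.ceil(ranks * n_bins / x.size).astype(np.int64) - 1
    elif method == "equal_width_bins":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.size, dtype=np.int64)
        codes = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    else:
        raise ContractError(f"unknown binning method: {method!r}")
    return np.clip(codes, 0, n_bins - 1)


def _marginal_stats(codes: np.ndarray, n_bins: int) -> tuple[float, int]:
    """Plug-in entropy (nats) and occupied-bin count of a code vector."""
    counts = np.bincount(codes, minlength=n_bins)
    p = counts / codes.size
    entropy = -np.sum(xlogy(p, p))
    return float(entropy), int(np.count_nonzero(counts))


def estimate_mi(x: np.ndarray, y: np.ndarray, cfg: EstimatorConfig | None = None) -> float:
    """Mutual information (nats) between two sample vectors.

    Constant inputs are degenerate under equal-frequency binning (one
    occupied bin): the estimate is 0 and a warning is logged.
    """
    cfg = cfg or EstimatorConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ContractError("inputs must be 1-D sample vectors")
    if x.size != y.size:
        raise ContractError(f"length mismatch: {x.size} vs {y.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ContractError("inputs contain NaN or infinity")
    n = x.size
    bins = cfg.resolve_bins(n)
    if n < 2 * bins:
        raise ContractError(f"need at least 2*n_bins={2 * bins} samples, got {n}")
    bx = bin_codes(x, bins, cfg.method)
    by = bin_codes(y, bins, cfg.method)
    hx, kx = _marginal_stats(bx, bins)
    hy, ky = _marginal_stats(by, bins)
    if kx == 1 or ky == 1:
        logger.warning("degenerate (constant) input vector: MI set to 0")
        return 0.0
    joint = np.bincount(bx * bins + by, minlength=bins * bins)
    pj = joint / n
    # sort the joint-entropy terms before summing: the sum becomes
    # invariant to transposing the joint table, making MI(x,y)==MI(y,x)
    # exact and the blocked matrix path bit-identical to this one
    hxy = -np.sum(np.sort(xlogy(pj, pj)))
    kxy = int(np.count_nonzero(joint))
    mi = (hx + hy) - hxy
    if cfg.bias_correction == "miller_madow":
        mi = mi + (kx + ky - kxy - 1) / (2.0 * n)
    return float(mi) if mi > 0.0 else 0.0


def compute_mi_matrix(
    expr: ExpressionMatrix,
    cfg: EstimatorConfig | None = None,
    n_workers: int = 1,
) -> MIMatrix:
    """Assemble the full off-diagonal MI matrix of an expression matrix.

    All ``N(N-1)/2`` unordered pairs are estimated once and mirrored;
    the diagonal is exactly zero. The result is bit-identical for any
    ``n_workers``.
    """
    cfg = cfg or EstimatorConfig()
    n_genes, n_samples = expr.n_genes, expr.n_samples
    if n_genes < 2:
        raise ContractError("MI matrix requires at least 2 genes")
    bins = cfg.resolve_bins(n_samples)
    if n_samples < 2 * bins:
        raise ContractError(
            f"need at least 2*n_bins={2 * bins} samples, got {n_samples}"
        )

    codes = np.empty((n_genes, n_samples), dtype=np.int64)
    entropies = np.empty(n_genes)
    occupied = np.empty(n_genes, dtype=np.int64)
    for g in range(n_genes):
        codes[g] = bin_codes(expr.values[g], bins, cfg.method)
        entropies[g], occupied[g] = _marginal_stats(codes[g], bins)
    n_constant = int(np.sum(occupied == 1))
    if n_constant:
        logger.warning("%d constant gene(s): their MI rows are 0", n_constant)

    matrix = np.zeros((n_genes, n_genes))
    sq = bins * bins

    def _fill_row(i: int) -> None:
        others = codes[i + 1:]
        m = others.shape[0]
        if m == 0:
            return
        flat = codes[i] * bins + others  # (m, n_samples)
        flat = flat + (np.arange(m, dtype=np.int64) * sq)[:, None]
        joint = np.bincount(flat.ravel(), minlength=m * sq).reshape(m, sq)
        pj = joint / n_samples
        hxy = -np.sum(np.sort(xlogy(pj, pj), axis=1), axis=1)
        mi = (entropies[i] + entropies[i + 1:]) - hxy
        if cfg.bias_correction == "miller_madow":
            kxy = np.count_nonzero(joint, axis=1)
            mi = mi + (occupied[i] + occupied[i + 1:] - kxy - 1) / (2.0 * n_samples)
        degenerate = (occupied[i] == 1) | (occupied[i + 1:] == 1)
        mi = np.where(mi > 0.0, mi, 0.0)
        mi[degenerate] = 0.0
        matrix[i, i + 1:] = mi

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            list(pool.map(_fill_row, range(n_genes - 1)))
    else:
        for i in range(n_genes - 1):
            _fill_row(i)

    matrix = matrix + matrix.T  # mirror; diagonal stays exactly 0
    meta = {
        "estimator": cfg.method,
        "n_bins": bins,
        "bias_correction": cfg.bias_correction,
        "log_base": "e",
        "n_samples": n_samples,
    }
    return MIMatrix(gene_ids=list(expr.gene_ids), values=matrix, estimator_meta=meta)


def permutation_null_mi(
    x: np.ndarray,
    y: np.ndarray,
    cfg: EstimatorConfig | None = None,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null MI values from seeded permutations of ``y`` against fixed ``x``."""
    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    cfg = cfg or EstimatorConfig()
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        null[p] = estimate_mi(x, y[rng.permutation(y.size)], cfg)
    return null
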