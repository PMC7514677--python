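"""Synthetic transcriptomes with known cis/trans dependency structure.

The generator emulates a paired tumor/control RNA-seq study: one gene
set annotated to chromosomes 1..22, X with heterogeneous chromosome
sizes, and two expression matrices drawn from a Gaussian latent-factor
model with

* one latent factor per chromosome (cis co-regulation),
* a shared trans factor — or one factor per configured chromosome
  group — coupling genes across chromosomes,
* i.i.d. Gaussian noise absorbing the remaining variance.

Coupling parameters are target pairwise correlations: two genes on the
same chromosome correlate at ``cis_coupling``; genes on different
chromosomes (sharing a trans factor) correlate at ``trans_coupling``.
Loadings are ``b = sqrt(t)`` on the trans factor and ``a = sqrt(c - t)``
on the chromosome factor, with residual sd ``noise_sd * sqrt(1 - c)``;
at the default ``noise_sd = 1`` every gene has unit marginal variance.
This factorization is the one in which weakening trans coupling leaves
cis pair correlations exactly unchanged — the "loss of
trans-regulation" phenotype contrast the tumor condition encodes.
Because factors are Gaussian, every pairwise MI is known in closed form
(``-0.5 * ln(1 - rho^2)``), which downstream tests exploit as an oracle.

Outputs are mapped to non-negative RNA-seq-like values by a monotone
affine transform (shift to zero minimum, scale x10), which leaves MI
under rank-based binning unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chromosomes import CHROMOSOMES, chrom_sort_key
from .errors import ConfigurationError, ContractError
from .io import ExpressionMatrix, GeneAnnotation
import pandas as pd

#: Approximate relative gene content of human chromosomes (protein-coding
#: gene counts; metacentric chromosomes such as 1, 11, 17, 19 carry several
#: times more genes than acrocentric ones such as 13, 18, 21).
DEFAULT_CHROMOSOME_WEIGHTS: dict[str, float] = {
    "1": 2000, "2": 1200, "3": 1000, "4": 750, "5": 900, "6": 1000,
    "7": 900, "8": 700, "9": 780, "10": 730, "11": 1300, "12": 1000,
    "13": 320, "14": 800, "15": 600, "16": 800, "17": 1200, "18": 270,
    "19": 1400, "20": 540, "21": 230, "22": 440, "X": 840,
}

#: Synthetic genome scale: chromosome length in bp per unit of weight
#: (weight 2000 -> 200 Mb, roughly chromosome 1).
_BP_PER_WEIGHT = 100_000


@dataclass
class SimulationConfig:
    """Study conditions for one paired tumor/control simulation.

    Defaults encode the trans-loss scenario: identical cis coupling in
    both conditions, trans coupling 0.5 in control and 0 in tumor, 300
    genes across the 23 canonical chromosomes, 100 samples per arm.
    ``cis_distance_decay_tumor`` optionally attenuates tumor cis
    loadings by ``exp(-decay * distance_to_chromosome_start)`` (per bp),
    emulating correlation strength that decays with genomic distance.
    ``trans_factor_groups`` optionally replaces the single global trans
    factor by one factor per listed chromosome group (chromosomes not
    listed get no trans coupling), for planted block structure.
    """

    n_genes: int = 300
    chromosome_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_WEIGHTS)
    )
    n_samples_control: int = 100
    n_samples_tumor: int = 100
    cis_coupling_control: float = 0.5
    cis_coupling_tumor: float = 0.5
    trans_coupling_control: float = 0.5
    trans_coupling_tumor: float = 0.0
    cis_distance_decay_tumor: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    trans_factor_groups: list[list[str]] | None = None

    def __post_init__(self) -> None:
        if not self.chromosome_weights:
            raise ConfigurationError("chromosome_weights must not be empty")
        unknown = set(self.chromosome_weights) - set(CHROMOSOMES)
        if unknown:
            raise ConfigurationError(f"unknown chromosome labels: {sorted(unknown)}")
        if any(w <= 0 for w in self.chromosome_weights.values()):
            raise ConfigurationError("chromosome weights must be positive")
        if self.n_genes < len(self.chromosome_weights):
            raise ConfigurationError(
                "n_genes must be at least the number of chromosomes"
            )
        if self.n_samples_control < 1 or self.n_samples_tumor < 1:
            raise ConfigurationError("sample counts must be positive")
        for name in (
            "cis_coupling_control", "cis_coupling_tumor",
            "trans_coupling_control", "trans_coupling_tumor",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        for cond in ("control", "tumor"):
            c = getattr(self, f"cis_coupling_{cond}")
            t = getattr(self, f"trans_coupling_{cond}")
            if t > c:
                raise ConfigurationError(
                    f"trans_coupling_{cond}={t} exceeds cis_coupling_{cond}={c}; "
                    "the shared trans factor cannot induce more within- than "
                    "cross-chromosome correlation"
                )
        if self.cis_distance_decay_tumor < 0:
            raise ConfigurationError("cis_distance_decay_tumor must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.trans_factor_groups is not None:
            flat = [c for group in self.trans_factor_groups for c in group]
            if len(flat) != len(set(flat)):
                raise ConfigurationError("trans_factor_groups must be disjoint")
            bad = set(flat) - set(self.chromosome_weights)
            if bad:
                raise ConfigurationError(
                    f"trans_factor_groups reference absent chromosomes: {sorted(bad)}"
                )


def apportion(n_genes: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of genes to chromosomes.

    Every chromosome with positive weight receives at least one gene;
    remainder ties are broken by lexicographic label order.
    """
    if not weights:
        raise ConfigurationError("chromosome_weights must not be empty")
    labels = sorted(weights)  # lexicographic tie order
    total_w = sum(weights[c] for c in labels)
    quotas = {c: n_genes * weights[c] / total_w for c in labels}
    counts = {c: math.floor(quotas[c]) for c in labels}
    leftover = n_genes - sum(counts.values())
    by_remainder = sorted(labels, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in by_remainder[:leftover]:
        counts[c] += 1
    # guarantee >= 1 by transferring from the largest allocation
    for c in labels:
        while counts[c] == 0:
            donor = max(labels, key=lambda d: (counts[d], d))
            counts[donor] -= 1
            counts[c] += 1
    return counts


def generate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Deterministic synthetic gene annotation for *config*.

    Gene counts per chromosome follow largest-remainder apportionment of
    ``chromosome_weights``; within each chromosome genes sit at strictly
    increasing, uniformly spaced start coordinates on a chromosome whose
    length is proportional to its weight (1 Mb-scale spacing).
    """
    counts = apportion(config.n_genes, config.chromosome_weights)
    rows = []
    gene_no = 0
    width = len(str(config.n_genes))
    for chrom in sorted(counts, key=chrom_sort_key):
        n_k = counts[chrom]
        length = int(config.chromosome_weights[chrom] * _BP_PER_WEIGHT)
        spacing = max(length // n_k, 2)
        for j in range(n_k):
            gene_no += 1
            start = j * spacing
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + min(1000, spacing - 1),
                    "gene_id": f"g{gene_no:0{width}d}",
                }
            )
    return GeneAnnotation(pd.DataFrame(rows))


def _trans_group_of(config: SimulationConfig, chromosomes: list[str]) -> dict[str, int]:
    """chromosome -> trans-factor index (-1: no trans factor)."""
    if config.trans_factor_groups is None:
        return {c: 0 for c in chromosomes}
    mapping = {c: -1 for c in chromosomes}
    for g, group in enumerate(config.trans_factor_groups):
        for c in group:
            mapping[c] = g
    return mapping


def _simulate_condition(
    annotation: GeneAnnotation,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    cis = getattr(config, f"cis_coupling_{condition}")
    trans = getattr(config, f"trans_coupling_{condition}")
    decay = config.cis_distance_decay_tumor if condition == "tumor" else 0.0
    n_samples = getattr(config, f"n_samples_{condition}")

    chroms = annotation.chromosomes()
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    group_of = _trans_group_of(config, chroms)
    n_groups = max(group_of.values()) + 1 if group_of else 0

    gene_chrom = annotation.table["chrom"].to_numpy()
    starts = annotation.table["start"].to_numpy(dtype=np.float64)
    n_genes = len(gene_chrom)

    cis_factors = rng.standard_normal((len(chroms), n_samples))
    trans_factors = (
        rng.standard_normal((n_groups, n_samples)) if n_groups > 0 else np.empty((0, n_samples))
    )
    noise = rng.standard_normal((n_genes, n_samples))

    a0 = math.sqrt(cis - trans)
    b0 = math.sqrt(trans)
    resid_sd = config.noise_sd * math.sqrt(1.0 - cis)
    scale = math.sqrt(cis + config.noise_sd**2 * (1.0 - cis))

    z = np.empty((n_genes, n_samples))
    for i in range(n_genes):
        chrom = gene_chrom[i]
        a_i = a0 * math.exp(-decay * starts[i])
        row = a_i * cis_factors[chrom_idx[chrom]] + resid_sd * noise[i]
        g = group_of[chrom]
        if g >= 0:
            row = row + b0 * trans_factors[g]
        z[i] = row / scale

    values = 10.0 * (z - z.min())  # monotone affine map to non-negative values
    prefix = "tum" if condition == "tumor" else "ctl"
    sample_ids = [f"{prefix}_s{j + 1:03d}" for j in range(n_samples)]
    return ExpressionMatrix(
        gene_ids=annotation.gene_ids,
        sample_ids=sample_ids,
        values=values,
        condition=condition,
    )


def generate_expression_pair(
    annotation: GeneAnnotation, config: SimulationConfig
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw (control, tumor) expression matrices sharing *annotation*.

    The two conditions are independent unpaired cohorts; all randomness
    derives from ``config.seed``, so identical inputs reproduce
    byte-identical matrices.
    """
    if set(annotation.chromosomes()) != set(config.chromosome_weights):
        raise ContractError(
            "annotation chromosomes do not match config.chromosome_weights"
        )
    if len(annotation.gene_ids) != config.n_genes:
        raise ContractError(
            f"annotation has {len(annotation.gene_ids)} genes, "
            f"config.n_genes={config.n_genes}"
        )
    ss = np.random.SeedSequence(config.seed)
    ctrl_ss, tum_ss = ss.spawn(2)
    control = _simulate_condition(
        annotation, config, "control", np.random.default_rng(ctrl_ss)
    )
    tumor = _simulate_condition(
        annotation, config, "tumor", np.random.default_rng(tum_ss)
    )
    return control, tumor
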