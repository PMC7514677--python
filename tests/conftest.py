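import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from grpspace import ExpressionMatrix, GeneAnnotation, MIMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def three_chrom_annotation() -> GeneAnnotation:
    """Six genes: chr1={g1,g2,g3}, chr2={g4,g5}, chrX={g6}."""
    return GeneAnnotation(
        pd.DataFrame(
            {
                "chrom": ["1", "1", "1", "2", "2", "X"],
                "start": [0, 100, 200, 0, 100, 0],
                "end": [50, 150, 250, 50, 150, 50],
                "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            }
        )
    )


@pytest.fixture
def random_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    n_genes, n_samples = 12, 60
    return ExpressionMatrix(
        gene_ids=[f"g{i:02d}" for i in range(n_genes)],
        sample_ids=[f"s{j:02d}" for j in range(n_samples)],
        values=np.abs(rng.standard_normal((n_genes, n_samples))),
    )


def make_symmetric_mi(gene_ids: list[str], seed: int = 0) -> MIMatrix:
    """Random symmetric non-negative matrix with zero diagonal."""
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    m = np.abs(rng.standard_normal((n, n)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return MIMatrix(gene_ids=gene_ids, values=m)
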