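import numpy as np
import pandas as pd
import pytest

from allometh.homoeolog import QuartetExpression, normalize_quartet_expression
from allometh.synthetic_data import (
    SimConfig,
    simulate_expression,
    simulate_genomes,
    simulate_methylomes,
)


@pytest.fixture(scope="session")
def meth_study():
    """Small methylome-focused study: ~1100 collinear windows per lineage."""
    cfg = SimConfig(n_quartets=2, chrom_length_bp=110_000, dmr_fraction=0.05, seed=5)
    bundle = simulate_genomes(cfg)
    samples, controls, truth = simulate_methylomes(bundle, cfg)
    return cfg, bundle, samples, controls, truth


@pytest.fixture(scope="session")
def expr_study():
    """Expression-focused study: 120 quartets, methylomes not simulated."""
    cfg = SimConfig(n_quartets=120, chrom_length_bp=360_000, seed=7)
    bundle = simulate_genomes(cfg)
    counts, sheet, truth = simulate_expression(bundle, cfg)
    return cfg, bundle, counts, sheet, truth


@pytest.fixture(scope="session")
def quartet_expr(expr_study):
    cfg, bundle, counts, sheet, truth = expr_study
    lengths = bundle.genes.set_index("gene_id")["length"]
    return normalize_quartet_expression(counts, lengths, bundle.quartets, sheet)


def qe_from_means(means: pd.DataFrame, n_par: int = 3, n_tet: int = 3) -> QuartetExpression:
    """Noise-free QuartetExpression: planted means copied across replicates."""

    def rep(col, prefix, n):
        vals = means[col].to_numpy(dtype=float)
        return pd.DataFrame(
            {f"{prefix}{i}": vals for i in range(1, n + 1)}, index=means.index
        )

    return QuartetExpression(
        a=rep("a_mean", "Ad_rna", n_par),
        b=rep("b_mean", "Ai_rna", n_par),
        at=rep("at_mean", "Ah_rna", n_tet),
        bt=rep("bt_mean", "Ah_rna", n_tet),
    )


def make_calls(rows):
    """Call table from (chrom, pos, strand, context, c, ct) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "c_count", "ct_count"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
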