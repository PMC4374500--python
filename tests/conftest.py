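import numpy as np
import pytest

from modmark import (
    CASE,
    NORMAL,
    ExpressionMatrix,
    PhenotypeLabels,
    PPINetwork,
    SyntheticSpec,
    generate_instance,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with simple integer values."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 2.0, 3.0, 4.0],
                  [0.0, 1.0, 0.0, 1.0],
                  [5.0, 4.0, 3.0, 2.0]]),
    )


@pytest.fixture
def tiny_labels() -> PhenotypeLabels:
    return PhenotypeLabels({"s1": NORMAL, "s2": NORMAL, "s3": CASE, "s4": CASE})


@pytest.fixture
def star_net() -> PPINetwork:
    return PPINetwork.from_edges([("a", "b"), ("a", "c"), ("a", "d")])


@pytest.fixture(scope="session")
def default_instance():
    """One synthetic benchmark instance at the default study conditions."""
    return generate_instance(SyntheticSpec(rng_seed=42))


def make_group_expr(rng, n_genes, n_per_group, shift_genes=(), shift=0.0):
    """Expression with i.i.d. N(0,1) noise and an optional CASE mean shift."""
    genes = [f"g{i}" for i in range(1, n_genes + 1)]
    samples = [f"s{i}" for i in range(1, 2 * n_per_group + 1)]
    vals = rng.standard_normal((n_genes, 2 * n_per_group))
    for g in shift_genes:
        vals[genes.index(g), n_per_group:] += shift
    labels = PhenotypeLabels(
        {s: (NORMAL if i < n_per_group else CASE) for i, s in enumerate(samples)}
    )
    return ExpressionMatrix(genes, samples, vals), labels
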