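import numpy as np
import pandas as pd
import pytest

from focusheur.data_io import ExpressionDataset, InteractionNetwork


def make_expression(values, genes, conditions=("healthy",) * 3 + ("disease",) * 3):
    """values: genes x samples array-like; conditions label the columns."""
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(
        pd.DataFrame(values, index=list(genes), columns=samples),
        pd.Series(list(conditions), index=samples),
    )


def make_network(edges, extra_nodes=()):
    """edges: iterable of (a, b) or (a, b, type) or (a, b, type, conf)."""
    full = []
    for e in edges:
        a, b = e[0], e[1]
        etype = e[2] if len(e) > 2 else "unspecified"
        conf = e[3] if len(e) > 3 else 1.0
        full.append((a, b, etype, conf))
    return InteractionNetwork.from_edges(full, extra_nodes=extra_nodes)


@pytest.fixture
def toy_expr():
    # gene A up, B down, C flat, D mildly up, E flat-high
    vals = [
        [2, 2, 2, 4, 4, 4],   # A: LFC +2
        [5, 5, 5, 3, 3, 3],   # B: LFC -2
        [1, 1, 1, 1, 1, 1],   # C: LFC 0
        [3, 3, 3, 3.5, 3.5, 3.5],  # D: LFC +0.5
        [8, 8, 8, 8, 8, 8],   # E: LFC 0, high expression
    ]
    return make_expression(vals, "ABCDE")


@pytest.fixture
def toy_net():
    return make_network(
        [("A", "B", "activation"), ("A", "C", "inhibition"),
         ("B", "D"), ("D", "E"), ("C", "E")]
    )


def random_instance(rng, n_genes=20, p_edge=0.15, replicates=3,
                    frac_inhibition=0.3):
    """A random expression + network pair sharing one gene universe."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    vals = rng.normal(5.0, 2.0, size=(n_genes, 2 * replicates))
    expr = make_expression(
        vals, genes, ("healthy",) * replicates + ("disease",) * replicates
    )
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p_edge:
                etype = "inhibition" if rng.random() < frac_inhibition else (
                    "activation" if rng.random() < 0.5 else "unspecified"
                )
                edges.append((genes[i], genes[j], etype, float(rng.uniform(0.5, 1))))
    net = InteractionNetwork.from_edges(edges, extra_nodes=genes)
    return expr, net
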