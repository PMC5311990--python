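"""Planted-module synthetic benchmarks.

The generator emulates the four benchmark inputs without any download:

* a scale-free interaction network (preferential attachment), because the
  hub/pleiotropy structure of curated interactomes is heavy-tailed;
* a log2 expression matrix with replicated healthy and disease samples in
  which one connected module carries a true expression shift
  (``effect_size`` log2 units, random sign per gene) on top of i.i.d.
  Gaussian noise, all other genes being null;
* a gold-standard gene–disease table whose positives overlap the planted
  module by a controlled fraction, plus degree-biased pleiotropic genes
  each annotated to ten or more pseudo-diseases (mirroring the observation
  that pleiotropic genes tend to be hubs);
* publication counts correlated with node degree.

One integer seed drives everything; per-component substreams are derived
deterministically from it, so repeated calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from focusheur.baselines import PmidCounts
from focusheur.data_io import (
    DiseaseGeneTable,
    ExpressionDataset,
    InteractionNetwork,
)

DISEASE_ID = "C0000001"

BASELINE_MEAN = 7.0  # typical log2 microarray intensity
BASELINE_SD = 1.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic benchmark instance.

    ``effect_size`` is the mean |LFC| of planted-module genes in log2
    units; ``noise_sd`` the per-sample Gaussian sd; ``gold_overlap`` the
    fraction of gold-standard genes drawn from the module (the rest are
    random decoys); ``pleiotropy_rate`` the fraction of genes annotated as
    pleiotropic (>= 10 pseudo-diseases), sampled with degree bias.
    """

    n_genes: int = 500
    attachment: int = 2
    module_size: int = 30
    effect_size: float = 2.0
    noise_sd: float = 0.5
    replicates: int = 3
    frac_inhibition: float = 0.0
    gold_overlap: float = 0.8
    gold_size: int | None = None
    pleiotropy_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.module_size <= self.n_genes):
            raise ValueError("module_size must lie in [0, n_genes]")
        if self.replicates < 3:
            raise ValueError("each condition needs at least 3 replicates")
        for name in ("frac_inhibition", "gold_overlap", "pleiotropy_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.attachment < 1 or self.attachment >= self.n_genes:
            raise ValueError("attachment must satisfy 1 <= m < n_genes")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticScenario":
        return cls(**dict(d))


@dataclass
class SyntheticInstance:
    network: InteractionNetwork
    expression: ExpressionDataset
    disease_genes: DiseaseGeneTable
    pmid: PmidCounts
    module: list[str] = field(default_factory=list)
    gold: list[str] = field(default_factory=list)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate(scn: SyntheticScenario) -> SyntheticInstance:
    """Build one full benchmark instance from a scenario."""
    ss = np.random.SeedSequence(scn.seed)
    s_topo, s_expr, s_gold, s_pleio, s_pmid = ss.spawn(5)
    rng_expr = np.random.default_rng(s_expr)
    rng_gold = np.random.default_rng(s_gold)
    rng_pleio = np.random.default_rng(s_pleio)
    rng_pmid = np.random.default_rng(s_pmid)

    # --- topology ---------------------------------------------------------
    topo_seed = int(s_topo.generate_state(1)[0] % (2**31 - 1))
    graph = nx.barabasi_albert_graph(scn.n_genes, scn.attachment, seed=topo_seed)
    mapping = {i: _gene_name(i) for i in graph.nodes}
    graph = nx.relabel_nodes(graph, mapping)
    rng_topo = np.random.default_rng(topo_seed)
    edges = []
    for a, b in sorted(graph.edges):
        etype = (
            "inhibition"
            if rng_topo.random() < scn.frac_inhibition
            else "unspecified"
        )
        conf = float(rng_topo.uniform(0.501, 1.0))
        edges.append((a, b, etype, conf))
    net = InteractionNetwork.from_edges(edges, extra_nodes=mapping.values())
    genes = sorted(net.nodes)

    # --- planted module (connected, via BFS from a random start) ----------
    module: list[str] = []
    if scn.module_size > 0:
        start = genes[int(rng_expr.integers(len(genes)))]
        for node in nx.bfs_tree(net.graph, start):
            module.append(node)
            if len(module) == scn.module_size:
                break
    module_set = set(module)

    # --- expression --------------------------------------------------------
    n_rep = scn.replicates
    baseline = rng_expr.normal(BASELINE_MEAN, BASELINE_SD, size=len(genes))
    shift = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in module_set:
            sign = 1.0 if rng_expr.random() < 0.5 else -1.0
            shift[i] = sign * scn.effect_size
    healthy = baseline[:, None] + rng_expr.normal(
        0.0, scn.noise_sd, size=(len(genes), n_rep)
    )
    disease = (baseline + shift)[:, None] + rng_expr.normal(
        0.0, scn.noise_sd, size=(len(genes), n_rep)
    )
    samples = [f"H{j + 1}" for j in range(n_rep)] + [f"D{j + 1}" for j in range(n_rep)]
    values = pd.DataFrame(
        np.hstack([healthy, disease]), index=genes, columns=samples
    )
    condition = pd.Series(
        ["healthy"] * n_rep + ["disease"] * n_rep, index=samples
    )
    expr = ExpressionDataset(values, condition)

    # --- gold standard -----------------------------------------------------
    n_gold = scn.gold_size if scn.gold_size is not None else scn.module_size
    n_gold = min(n_gold, len(genes))
    n_from_module = min(int(round(scn.gold_overlap * n_gold)), len(module))
    gold = list(
        rng_gold.choice(sorted(module_set), size=n_from_module, replace=False)
    ) if n_from_module else []
    others = sorted(set(genes) - module_set)
    n_rest = min(n_gold - n_from_module, len(others))
    if n_rest > 0:
        gold += list(rng_gold.choice(others, size=n_rest, replace=False))
    gold = sorted(gold)

    records = [(g, DISEASE_ID) for g in gold]

    # --- pleiotropy: degree-biased genes with >= 10 pseudo-diseases --------
    degrees = np.array([net.graph.degree(g) for g in genes], dtype=float)
    n_pleio = int(round(scn.pleiotropy_rate * len(genes)))
    if n_pleio > 0:
        weights = degrees + 1.0
        pleio_genes = rng_pleio.choice(
            genes, size=n_pleio, replace=False, p=weights / weights.sum()
        )
        pool = [f"CP{k:04d}" for k in range(50)]
        for g in sorted(pleio_genes):
            n_dis = 10 + int(rng_pleio.poisson(3))
            for d in rng_pleio.choice(pool, size=min(n_dis, len(pool)), replace=False):
                records.append((g, d))
    disease_table = DiseaseGeneTable(
        pd.DataFrame(records, columns=["gene", "disease"])
    )

    # --- publication counts correlated with degree -------------------------
    counts = {
        g: int(rng_pmid.poisson(5.0 * degrees[i]))
        for i, g in enumerate(genes)
    }
    pmid = PmidCounts(counts)

    return SyntheticInstance(
        network=net,
        expression=expr,
        disease_genes=disease_table,
        pmid=pmid,
        module=module,
        gold=gold,
    )


def permuted_controls(
    expr: ExpressionDataset, n_controls: int, seed: int
) -> list[ExpressionDataset]:
    """Label-permuted control datasets for the disease-specificity analysis.

    Each control reassigns the healthy/disease labels to a random
    permutation of the samples, destroying the planted contrast. The
    identity assignment and its full complement are excluded: the
    complement merely flips every LFC sign, which the magnitude-based
    condensation cannot distinguish from the matched data.
    """
    rng = np.random.default_rng(seed)
    samples = list(expr.values.columns)
    labels = expr.condition.loc[samples].to_numpy()
    original = tuple(labels)
    complement = tuple(
        "healthy" if c == "disease" else "disease" for c in labels
    )
    controls = []
    attempts = 0
    while len(controls) < n_controls:
        attempts += 1
        if attempts > 1000 * n_controls:
            raise RuntimeError("cannot draw enough distinct label permutations")
        perm = tuple(rng.permutation(labels))
        if perm in (original, complement):
            continue
        condition = pd.Series(list(perm), index=samples)
        controls.append(ExpressionDataset(expr.values, condition))
    return controls
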