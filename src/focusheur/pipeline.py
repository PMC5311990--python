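"""End-to-end benchmark driver: inputs -> rankings -> evaluation tables.

Wires the pipeline the way the command-line interface exposes it:
simulate (or load) -> score -> rank -> baselines -> evaluate. Every output
row is traceable to a (method, dataset, variant) triple and the run is
deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from focusheur.baselines import BASELINE_BUILDERS, PmidCounts
from focusheur.condense import METHOD_NAME, focus_ranking
from focusheur.data_io import (
    DiseaseGeneTable,
    ExpressionDataset,
    InteractionNetwork,
    intersect_universe,
    load_disease_genes,
    load_expression,
    load_id_map,
    load_network,
    load_pmid_counts,
)
from focusheur.evaluation import (
    AucResult,
    auc_of_ranking,
    make_reference,
    restrict_top,
    similarity_matrix,
    specificity_fraction,
)
from focusheur.ranking import GeneRanking
from focusheur.synthetic import SyntheticScenario, generate, permuted_controls

logger = logging.getLogger(__name__)

FOCUS_KEY = "focusheuristics"
KNOWN_METHODS = (FOCUS_KEY,) + tuple(BASELINE_BUILDERS)


@dataclass
class RunConfig:
    """Paths (or a scenario) plus the benchmark's tunable parameters."""

    network: str | None = None
    expression: str | None = None
    conditions: str | None = None
    disease_genes: str | None = None
    pmid: str | None = None
    id_map: str | None = None
    scenario: SyntheticScenario | None = None
    min_confidence: float = 0.5
    grid: int = 200
    pleiotropy_cutoff: int = 10
    top_fraction: float = 0.01
    methods: tuple[str, ...] = KNOWN_METHODS
    n_controls: int = 10
    seed: int = 0
    out_dir: str = "focusheur_out"

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(
                f"unknown methods {unknown}; choose from {list(KNOWN_METHODS)}"
            )
        if self.scenario is None and (self.network is None or self.expression is None):
            raise ValueError("either a scenario or network+expression paths required")


def load_inputs(
    cfg: RunConfig,
) -> tuple[InteractionNetwork, ExpressionDataset, DiseaseGeneTable | None, PmidCounts]:
    if cfg.scenario is not None:
        inst = generate(cfg.scenario)
        return inst.network, inst.expression, inst.disease_genes, inst.pmid
    id_map = load_id_map(cfg.id_map) if cfg.id_map else None
    net = load_network(cfg.network, min_confidence=cfg.min_confidence, id_map=id_map)
    expr = load_expression(cfg.expression, cfg.conditions)
    table = load_disease_genes(cfg.disease_genes) if cfg.disease_genes else None
    pmid = PmidCounts(dict(load_pmid_counts(cfg.pmid))) if cfg.pmid else PmidCounts()
    return net, expr, table, pmid


def compute_rankings(
    expr: ExpressionDataset,
    net: InteractionNetwork,
    pmid: PmidCounts,
    methods: Sequence[str],
    grid: int = 200,
) -> dict[str, GeneRanking]:
    """All requested method rankings on the shared gene universe."""
    expr_u, net_u, _ = intersect_universe(expr, net)
    from focusheur.scoring import score_network

    gscores, _ = score_network(expr_u, net_u)
    out: dict[str, GeneRanking] = {}
    for m in methods:
        if m == FOCUS_KEY:
            out[METHOD_NAME] = focus_ranking(expr_u, net_u, n_levels=grid)
        else:
            ranking = BASELINE_BUILDERS[m](net_u, gscores, pmid)
            out[ranking.method] = ranking
    return out


def evaluate_rankings(
    rankings: Mapping[str, GeneRanking],
    table: DiseaseGeneTable,
    universe: Sequence[str],
    dataset: str = "dataset",
    pleiotropy_cutoff: int = 10,
    top_fraction: float = 0.01,
) -> list[AucResult]:
    """AUCs for every (method, disease, complete/reduced x all/top) cell."""
    import warnings

    from focusheur.evaluation import EmptyReferenceWarning

    results: list[AucResult] = []
    for disease in table.diseases:
        for variant in ("complete", "reduced"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyReferenceWarning)
                ref = make_reference(
                    table, disease, universe, variant, pleiotropy_cutoff
                )
            n_pos = len(ref.positives)
            if n_pos == 0 or n_pos == len(universe):
                logger.info("skipping %s/%s: degenerate positives", disease, variant)
                continue
            for name, ranking in rankings.items():
                results.append(
                    AucResult(name, dataset, disease, f"{variant}/all",
                              auc_of_ranking(ranking, ref))
                )
                results.append(
                    AucResult(
                        name, dataset, disease, f"{variant}/top",
                        auc_of_ranking(restrict_top(ranking, top_fraction), ref),
                    )
                )
    return results


def auc_frame(results: Sequence[AucResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def run_benchmark(cfg: RunConfig) -> Path:
    """Run the full pipeline and write all result tables to cfg.out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("focusheur")
    root.addHandler(handler)
    try:
        net, expr, table, pmid = load_inputs(cfg)
        expr_u, net_u, universe = intersect_universe(expr, net)
        logger.info("universe: %d genes, %d edges", len(universe), net_u.n_edges)

        rankings = compute_rankings(expr_u, net_u, pmid, cfg.methods, cfg.grid)
        rank_dir = out / "rankings"
        rank_dir.mkdir(exist_ok=True)
        for name, ranking in rankings.items():
            safe = name.replace("/", "-")
            ranking.write(str(rank_dir / f"{safe}.tsv"))

        if table is not None and not table.records.empty:
            results = evaluate_rankings(
                rankings, table, universe,
                dataset="scenario" if cfg.scenario is not None else "input",
                pleiotropy_cutoff=cfg.pleiotropy_cutoff,
                top_fraction=cfg.top_fraction,
            )
            auc_frame(results).to_csv(out / "auc.tsv", sep="\t", index=False)

            if cfg.scenario is not None and cfg.n_controls > 0:
                import warnings

                from focusheur.evaluation import EmptyReferenceWarning

                spec_rows = []
                controls = permuted_controls(expr_u, cfg.n_controls, cfg.seed)
                for disease in table.diseases:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", EmptyReferenceWarning)
                        ref = make_reference(
                            table, disease, universe, "reduced",
                            cfg.pleiotropy_cutoff,
                        )
                    if not ref.positives:
                        continue
                    for m in cfg.methods:
                        frac = specificity_fraction(
                            _method_callable(m, pmid, cfg.grid),
                            net_u, expr_u, controls, ref,
                        )
                        spec_rows.append(
                            {"method": m, "disease": disease, "specificity": frac}
                        )
                pd.DataFrame(spec_rows).to_csv(
                    out / "specificity.tsv", sep="\t", index=False
                )

        if len(rankings) >= 2:
            sim = similarity_matrix({"dataset": rankings})
            sim.values.to_csv(out / "similarity.tsv", sep="\t")

        with open(out / "config.json", "w") as fh:
            cfg_dict = asdict(cfg)
            json.dump(cfg_dict, fh, indent=2, default=str)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _method_callable(name: str, pmid: PmidCounts, grid: int):
    """A RankingMethod closure recomputing the ranking on a given dataset."""
    if name == FOCUS_KEY:
        return lambda expr, net: focus_ranking(expr, net, n_levels=grid)

    def run(expr: ExpressionDataset, net: InteractionNetwork) -> GeneRanking:
        from focusheur.scoring import score_network

        gscores, _ = score_network(expr, net)
        return BASELINE_BUILDERS[name](net, gscores, pmid)

    return run
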