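"""Input formats, identifier mapping and network preprocessing.

Four tabular inputs are supported:

* an interaction network as a tab-separated edge list
  (``geneA\\tgeneB[\\ttype][\\tconfidence]``), including the STRING
  protein-links dialect (space-separated, header ``protein1 protein2
  combined_score``, integer scores on a 0–1000 scale);
* a log2 expression matrix (genes x samples) with a two-column
  ``sample\\tcondition`` file labelling each sample ``healthy`` or
  ``disease``;
* a gene–disease association table (``gene\\tdiseaseId``), the flat-file
  subset of DisGeNet;
* a two-column identifier map (e.g. ENSP protein id -> HUGO symbol).

Preprocessing follows the benchmark conventions: self-loops and duplicate
edges are removed, edges are kept only when their confidence is strictly
above the cutoff, and all downstream analysis is restricted to the gene
universe present in both the expression data and the network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

HEALTHY = "healthy"
DISEASE = "disease"
CONDITIONS = (HEALTHY, DISEASE)

EDGE_TYPES = ("activation", "inhibition", "unspecified")


class ParseError(ValueError):
    """A malformed cell or row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(ValueError):
    """A required column is missing."""


class ValidationError(ValueError):
    """An input violates a dataset invariant."""


class EmptyUniverseError(ValueError):
    """The expression data and the network share no genes."""


class EmptyNetworkWarning(UserWarning):
    """The confidence filter removed every edge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionDataset:
    """A log2 expression matrix with a two-level condition design.

    ``values`` is genes x samples; ``condition`` maps every sample id to
    ``"healthy"`` or ``"disease"``. Each condition must have at least three
    replicates and all values must be finite.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes)[:5]}")
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise ValidationError(f"samples without a condition label: {missing}")
        bad = set(self.condition.loc[list(self.values.columns)]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        for cond in CONDITIONS:
            n = int((self.condition.loc[list(self.values.columns)] == cond).sum())
            if n < 3:
                raise ValidationError(
                    f"condition {cond!r} has {n} replicates; at least 3 required"
                )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, cond: str) -> list[str]:
        labels = self.condition.loc[list(self.values.columns)]
        return [s for s in self.values.columns if labels[s] == cond]

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionDataset(self.values.loc[keep], self.condition)

    def swap_conditions(self) -> "ExpressionDataset":
        """Relabel healthy<->disease (used for antisymmetry checks)."""
        flipped = self.condition.map({HEALTHY: DISEASE, DISEASE: HEALTHY})
        return ExpressionDataset(self.values, flipped)


class InteractionNetwork:
    """An undirected, typed, confidence-weighted gene graph.

    Invariants: no self-loops, unordered-pair edge uniqueness (duplicates
    collapse keeping the maximum confidence), every endpoint is a node.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for a, b, etype, conf in edges:
            if a == b:
                continue
            if etype not in EDGE_TYPES:
                raise ValidationError(f"unknown edge type {etype!r} on ({a},{b})")
            if g.has_edge(a, b):
                if conf > g.edges[a, b]["confidence"]:
                    g.edges[a, b].update(type=etype, confidence=conf)
            else:
                g.add_edge(a, b, type=etype, confidence=conf)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_list(self) -> list[tuple[str, str, str, float]]:
        """Edges as (gene_a, gene_b, type, confidence), endpoints sorted."""
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, data["type"], data["confidence"]))
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def restrict_nodes(self, genes: Iterable[str]) -> "InteractionNetwork":
        keep = set(genes) & self.nodes
        return InteractionNetwork(self.graph.subgraph(keep).copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_list() == other.edge_list()


@dataclass
class DiseaseGeneTable:
    """Unique (gene, disease id) association pairs."""

    records: pd.DataFrame  # columns: gene, disease

    def __post_init__(self) -> None:
        self.records = (
            self.records[["gene", "disease"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def pleiotropy(self) -> pd.Series:
        """Number of distinct diseases per gene."""
        if self.records.empty:
            return pd.Series(dtype=int, name="pleiotropy")
        return self.records.groupby("gene")["disease"].nunique().rename("pleiotropy")

    def genes_for(self, disease: str) -> set[str]:
        return set(self.records.loc[self.records["disease"] == disease, "gene"])

    @property
    def diseases(self) -> list[str]:
        return sorted(self.records["disease"].unique())


@dataclass
class IdMap:
    """Source identifier -> gene symbol; unmapped lookups are counted."""

    mapping: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    def translate(self, identifier: str) -> str | None:
        symbol = self.mapping.get(identifier)
        if symbol is None:
            self.unmapped.add(identifier)
        return symbol


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_network(
    path: str,
    min_confidence: float = 0.0,
    id_map: IdMap | None = None,
) -> InteractionNetwork:
    """Read an edge list, translating ids and applying the standard cleanup.

    Edges with confidence <= ``min_confidence`` are dropped (the filter is
    strictly-above, so a score exactly at the cutoff is removed), self-loops
    are discarded and duplicate unordered pairs collapse keeping the maximum
    confidence. STRING's integer combined_score dialect (values > 1) is
    detected automatically and rescaled to [0, 1].
    """
    rows: list[tuple[str, str, str, float, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields_ = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and _looks_like_network_header(fields_):
                continue
            if len(fields_) < 2:
                raise ParseError("expected at least two columns", line=lineno)
            a, b = fields_[0], fields_[1]
            etype = "unspecified"
            conf = 1.0
            rest = fields_[2:]
            if rest and rest[0] in EDGE_TYPES:
                etype = rest[0]
                rest = rest[1:]
            if rest:
                try:
                    conf = float(rest[0])
                except ValueError as exc:
                    raise ParseError(
                        f"confidence {rest[0]!r} is not numeric", line=lineno
                    ) from exc
            rows.append((a, b, etype, conf, lineno))

    # STRING combined_score comes as an integer in 0..1000
    if any(conf > 1.0 for _, _, _, conf, _ in rows):
        rows = [(a, b, t, c / 1000.0, ln) for a, b, t, c, ln in rows]

    edges = []
    n_unmapped = 0
    for a, b, etype, conf, lineno in rows:
        if id_map is not None:
            a2, b2 = id_map.translate(a), id_map.translate(b)
            if a2 is None or b2 is None:
                n_unmapped += 1
                continue
            a, b = a2, b2
        if conf > min_confidence:
            edges.append((a, b, etype, conf))
    if n_unmapped:
        logger.info("load_network: dropped %d edges with unmapped ids", n_unmapped)

    net = InteractionNetwork.from_edges(edges)
    if rows and net.n_edges == 0:
        warnings.warn(
            f"all {len(rows)} edges removed by min_confidence={min_confidence}",
            EmptyNetworkWarning,
            stacklevel=2,
        )
    return net


def _looks_like_network_header(fields_: list[str]) -> bool:
    head = [f.lower() for f in fields_[:2]]
    return head[:2] in (["protein1", "protein2"], ["genea", "geneb"], ["gene1", "gene2"])


def load_expression(path: str, condition_path: str | None = None) -> ExpressionDataset:
    """Read a TSV expression matrix plus its sample -> condition labels.

    The first column holds gene symbols; the header holds sample ids.
    Conditions come from a two-column ``sample\\tcondition`` file, or from
    header cells of the form ``sample:condition`` when no file is given.
    Duplicate gene rows are collapsed by their mean (probe-to-gene collapse)
    and genes with any missing value are dropped; both counts are logged.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)

    if condition_path is not None:
        cond_frame = pd.read_csv(
            condition_path, sep="\t", header=None, names=["sample", "condition"],
            dtype=str, comment="#",
        )
        if (
            not cond_frame.empty
            and cond_frame.iloc[0]["sample"].lower() == "sample"
        ):
            cond_frame = cond_frame.iloc[1:]
        condition = cond_frame.set_index("sample")["condition"]
    else:
        samples, labels = [], []
        for col in frame.columns:
            if ":" not in col:
                raise SchemaError(
                    f"sample {col!r} carries no ':condition' annotation and no "
                    "condition file was given"
                )
            s, c = col.rsplit(":", 1)
            samples.append(s)
            labels.append(c)
        frame.columns = samples
        condition = pd.Series(labels, index=samples)

    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {frame[col].iloc[i]!r} at gene "
                f"{frame.index[i]!r}, sample {col!r} (row {i + 2}, column {j + 2})"
            )
        numeric[col] = converted

    n_dup = int(numeric.index.duplicated().sum())
    if n_dup:
        numeric = numeric.groupby(level=0, sort=False).mean()
        logger.info("load_expression: collapsed %d duplicate gene rows by mean", n_dup)

    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        numeric = numeric.dropna(axis=0)
        logger.info(
            "load_expression: dropped %d genes with missing values", n_missing
        )

    return ExpressionDataset(numeric, condition)


def load_disease_genes(path: str) -> DiseaseGeneTable:
    """Read a gene–disease association table (DisGeNet flat-file subset)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    gene_col = _find_column(frame, ("gene", "genesymbol", "gene_symbol"))
    dis_col = _find_column(frame, ("diseaseid", "disease_id", "disease", "cui"))
    if gene_col is None or dis_col is None:
        if len(frame.columns) == 2:
            gene_col, dis_col = frame.columns
        else:
            raise SchemaError(
                f"cannot identify gene/disease columns among {list(frame.columns)}"
            )
    records = frame[[gene_col, dis_col]].dropna()
    records.columns = ["gene", "disease"]
    return DiseaseGeneTable(records)


def _find_column(frame: pd.DataFrame, candidates: tuple[str, ...]) -> str | None:
    lowered = {str(c).lower(): c for c in frame.columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def load_id_map(path: str) -> IdMap:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["source", "symbol"], dtype=str,
        comment="#",
    )
    if not frame.empty and frame.iloc[0]["source"].lower() in ("source", "id", "protein"):
        frame = frame.iloc[1:]
    return IdMap(dict(zip(frame["source"], frame["symbol"])))


def load_pmid_counts(path: str) -> Mapping[str, int]:
    """gene2pubmed-style two-column table: gene symbol, publication count."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "count"], dtype=str, comment="#",
    )
    if not frame.empty and frame.iloc[0]["gene"].lower() == "gene":
        frame = frame.iloc[1:]
    return {g: int(c) for g, c in zip(frame["gene"], frame["count"])}


# ---------------------------------------------------------------------------
# Universe intersection
# ---------------------------------------------------------------------------


def intersect_universe(
    expr: ExpressionDataset, net: InteractionNetwork
) -> tuple[ExpressionDataset, InteractionNetwork, list[str]]:
    """Restrict both inputs to the genes present in each.

    Every ranking method and the evaluation operate on this common gene
    universe; an edge survives only when both endpoints do.
    """
    universe = sorted(set(expr.gene_ids) & net.nodes)
    if not universe:
        raise EmptyUniverseError(
            "expression data and network share no genes; check identifier mapping"
        )
    return expr.restrict_genes(universe), net.restrict_nodes(universe), universe


# ---------------------------------------------------------------------------
# Writers (round-trip serialization)
# ---------------------------------------------------------------------------


def write_network(net: InteractionNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\ttype\tconfidence\n")
        for a, b, etype, conf in net.edge_list():
            fh.write(f"{a}\t{b}\t{etype}\t{conf:.6g}\n")


def write_expression(expr: ExpressionDataset, path: str, condition_path: str) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    expr.condition.loc[list(expr.values.columns)].rename("condition").to_csv(
        condition_path, sep="\t", header=False
    )


def write_disease_genes(table: DiseaseGeneTable, path: str) -> None:
    out = table.records.rename(columns={"disease": "diseaseId"})
    out.to_csv(path, sep="\t", index=False)
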