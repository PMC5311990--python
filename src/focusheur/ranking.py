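"""GeneRanking — the common currency every prioritization method emits.

A ranking is an ordered gene list partitioned into tie groups. Tie groups
are first-class: the threshold-sweep ranking admits whole batches of genes
per level, and the ROC evaluation advances a whole tie group as a single
diagonal segment. The within-group order is deterministic (for reproducible
output files) but carries no information the evaluator uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class GeneRanking:
    genes: list[str]
    tie_group: list[int]  # 1-based, nondecreasing along `genes`
    method: str = "unnamed"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.tie_group):
            raise ValueError("genes and tie_group lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")
        tg = np.asarray(self.tie_group)
        if len(tg) and (np.diff(tg) < 0).any():
            raise ValueError("tie_group must be nondecreasing in rank order")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def universe(self) -> list[str]:
        return list(self.genes)

    @property
    def n_groups(self) -> int:
        return self.tie_group[-1] if self.tie_group else 0

    def ranks(self) -> pd.Series:
        """Competition ranks: 1..N, every member of a tie group sharing the
        rank of the group's first position."""
        tg = np.asarray(self.tie_group)
        out = np.empty(len(tg), dtype=int)
        start = 0
        for gid in range(1, self.n_groups + 1):
            size = int((tg == gid).sum())
            out[start : start + size] = start + 1
            start += size
        return pd.Series(out, index=self.genes, name="rank")

    def midranks(self) -> pd.Series:
        """Average 1-based position within each tie group (Spearman input)."""
        tg = np.asarray(self.tie_group)
        out = np.empty(len(tg), dtype=float)
        start = 0
        for gid in range(1, self.n_groups + 1):
            size = int((tg == gid).sum())
            out[start : start + size] = start + (size + 1) / 2.0
            start += size
        return pd.Series(out, index=self.genes, name="midrank")

    def groups(self) -> list[list[str]]:
        tg = np.asarray(self.tie_group)
        return [
            [g for g, t in zip(self.genes, tg) if t == gid]
            for gid in range(1, self.n_groups + 1)
        ]

    @classmethod
    def from_scores(
        cls,
        scores: Mapping[str, float] | pd.Series,
        method: str = "unnamed",
        ascending: bool = False,
        tol: float = 1e-8,
    ) -> "GeneRanking":
        """Rank by score (descending by default); near-equal scores tie.

        ``tol`` absorbs iteration noise from numerical centralities
        (PageRank/HITS run to 1e-9): consecutive scores within
        ``tol * max(1, |score|)`` of the group's first member share a tie
        group. Within a tie group genes are ordered lexicographically for
        deterministic serialization.
        """
        series = pd.Series(scores, dtype=float)
        order = sorted(
            series.index, key=lambda g: (series[g] if ascending else -series[g], g)
        )
        tie_group: list[int] = []
        gid = 0
        anchor: float | None = None
        for g in order:
            val = float(series[g])
            if anchor is None or abs(val - anchor) > tol * max(1.0, abs(anchor)):
                gid += 1
                anchor = val
            tie_group.append(gid)
        return cls(genes=order, tie_group=tie_group, method=method)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "rank": self.ranks().to_numpy(),
                "gene": self.genes,
                "tie_group": self.tie_group,
            }
        )
        for key, values in self.extra.items():
            frame[key] = [values.get(g) for g in self.genes]
        return frame

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_ranking(path: str, method: str | None = None) -> GeneRanking:
    frame = pd.read_csv(path, sep="\t")
    return GeneRanking(
        genes=list(frame["gene"].astype(str)),
        tie_group=list(frame["tie_group"].astype(int)),
        method=method or "imported",
    )


def spearman_between(r1: GeneRanking, r2: GeneRanking) -> float:
    """Spearman rank correlation of two rankings over their shared universe,
    with average-rank (midrank) tie handling. NaN when either is constant."""
    shared = sorted(set(r1.genes) & set(r2.genes))
    if len(shared) < 2:
        return float("nan")
    m1 = r1.midranks().loc[shared].to_numpy()
    m2 = r2.midranks().loc[shared].to_numpy()
    if np.ptp(m1) == 0 or np.ptp(m2) == 0:
        return float("nan")
    from scipy.stats import spearmanr

    return float(spearmanr(m1, m2).statistic)


def check_same_universe(rankings: Sequence[GeneRanking]) -> None:
    base = set(rankings[0].genes)
    for r in rankings[1:]:
        if set(r.genes) != base:
            raise ValueError(
                f"rankings {rankings[0].method!r} and {r.method!r} cover "
                "different universes"
            )
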