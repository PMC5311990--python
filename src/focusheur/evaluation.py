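"""Benchmarking rankings against gold-standard gene sets.

The ROC curve sweeps every possible cut of a ranked gene list and plots the
true-positive rate against the false-positive rate; tied genes (one tie
group) are admitted together, producing one diagonal segment. The
trapezoidal area under this curve equals the Mann–Whitney probability that
a random positive is ranked above a random negative, with ties counted 1/2
(midrank convention).

Reference sets come in a complete and a reduced variant: the reduced
variant masks pleiotropic genes — genes associated with at least
``pleiotropy_cutoff`` (default 10) distinct diseases — because those are
predictable from connectivity alone and say little about disease
specificity. A further variant restricts each method to its top-ranked
fraction (default 1%), collapsing the remainder into one terminal tie
group so the AUC stays on the full universe and remains comparable across
methods.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from focusheur.data_io import (
    DiseaseGeneTable,
    ExpressionDataset,
    InteractionNetwork,
    intersect_universe,
)
from focusheur.ranking import GeneRanking, spearman_between

logger = logging.getLogger(__name__)

PLEIOTROPY_CUTOFF = 10
TOP_FRACTION = 0.01


class EmptyReferenceWarning(UserWarning):
    """A disease has no positives inside the universe."""


@dataclass(frozen=True)
class ReferenceSet:
    disease: str
    positives: frozenset[str]
    variant: str = "complete"  # or "reduced"


@dataclass(frozen=True)
class RocCurve:
    """Monotone staircase from (0,0) to (1,1); ties are diagonal segments."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.fpr, self.tpr):
            if arr[0] != 0.0 or arr[-1] != 1.0 or (np.diff(arr) < 0).any():
                raise ValueError("ROC coordinates must run nondecreasing 0 -> 1")


@dataclass(frozen=True)
class AucResult:
    method: str
    dataset: str
    disease: str
    variant: str  # e.g. "reduced/top1pct"
    auc: float


@dataclass(frozen=True)
class SimilarityMatrix:
    """Mean pairwise Spearman correlation of method rankings across datasets."""

    methods: tuple[str, ...]
    values: pd.DataFrame  # symmetric, diagonal 1

    def distance(self) -> pd.DataFrame:
        return 1.0 - self.values


def make_reference(
    table: DiseaseGeneTable,
    disease: str,
    universe: Sequence[str],
    variant: str = "complete",
    pleiotropy_cutoff: int = PLEIOTROPY_CUTOFF,
) -> ReferenceSet:
    """Positives for one disease, intersected with the universe.

    The reduced variant masks genes whose pleiotropy (distinct associated
    diseases in the full table) reaches the cutoff.
    """
    if variant not in ("complete", "reduced"):
        raise ValueError("variant must be 'complete' or 'reduced'")
    positives = table.genes_for(disease) & set(universe)
    if variant == "reduced":
        pleio = table.pleiotropy()
        positives = {
            g for g in positives if int(pleio.get(g, 0)) < pleiotropy_cutoff
        }
    if not positives:
        warnings.warn(
            f"disease {disease!r}: no {variant} positives in the universe",
            EmptyReferenceWarning,
            stacklevel=2,
        )
    return ReferenceSet(disease=disease, positives=frozenset(positives), variant=variant)


def roc(ranking: GeneRanking, ref: ReferenceSet) -> RocCurve:
    """ROC over all cuts of the ranked list; one point per tie group."""
    extra = ref.positives - set(ranking.genes)
    if extra:
        raise ValueError(
            f"{len(extra)} reference genes missing from the ranking universe"
        )
    n_pos = len(ref.positives)
    n_neg = len(ranking) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"degenerate reference: {n_pos} positives, {n_neg} negatives"
        )
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    for group in ranking.groups():
        hits = sum(1 for g in group if g in ref.positives)
        tp += hits
        fp += len(group) - hits
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    return RocCurve(fpr=np.asarray(fpr), tpr=np.asarray(tpr))


def auc(curve: RocCurve) -> float:
    """Trapezoidal area; equals P(pos above neg) + 1/2 P(tie)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_of_ranking(ranking: GeneRanking, ref: ReferenceSet) -> float:
    return auc(roc(ranking, ref))


def restrict_top(ranking: GeneRanking, fraction: float = TOP_FRACTION) -> GeneRanking:
    """Keep the top ceil(fraction * N) genes; all others collapse into one
    terminal tie group, so the ROC stays defined on the full universe."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    n = len(ranking)
    k = math.ceil(fraction * n)
    if k >= n:
        return ranking
    head_groups = list(ranking.tie_group[:k])
    tail_gid = (head_groups[-1] if head_groups else 0) + 1
    tie_group = head_groups + [tail_gid] * (n - k)
    return GeneRanking(
        genes=list(ranking.genes),
        tie_group=tie_group,
        method=ranking.method,
    )


RankingMethod = Callable[[ExpressionDataset, InteractionNetwork], GeneRanking]


def specificity_fraction(
    method: RankingMethod,
    net: InteractionNetwork,
    matched: ExpressionDataset,
    controls: Sequence[ExpressionDataset],
    ref: ReferenceSet,
    top_fraction: float | None = None,
) -> float:
    """Fraction of control (mismatched) datasets whose AUC falls strictly
    below the matched dataset's AUC, for one method and one reference set.

    Expression-independent methods land near 0 (all AUCs tie, and a tie
    counts as not-lower); disease-specific methods approach 1.
    """
    if not controls:
        raise ValueError("at least one control dataset is required")

    def run(expr: ExpressionDataset) -> float:
        expr_u, net_u, universe = intersect_universe(expr, net)
        ranking = method(expr_u, net_u)
        if top_fraction is not None:
            ranking = restrict_top(ranking, top_fraction)
        positives = ref.positives & set(universe)
        return auc_of_ranking(
            ranking, ReferenceSet(ref.disease, frozenset(positives), ref.variant)
        )

    matched_auc = run(matched)
    below = sum(1 for ctrl in controls if run(ctrl) < matched_auc)
    return below / len(controls)


def similarity_matrix(
    rankings: Mapping[str, Mapping[str, GeneRanking]],
) -> SimilarityMatrix:
    """Method x method mean Spearman correlation across datasets.

    ``rankings`` maps dataset id -> method name -> GeneRanking; all methods
    on one dataset must share a universe. A fully tied ranking has no
    defined correlation; such pairs are excluded from the mean with a log
    entry.
    """
    methods = sorted({m for per_ds in rankings.values() for m in per_ds})
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    acc = pd.DataFrame(0.0, index=methods, columns=methods)
    cnt = pd.DataFrame(0, index=methods, columns=methods)
    for ds, per_method in rankings.items():
        for m1, m2 in itertools.combinations(sorted(per_method), 2):
            rho = spearman_between(per_method[m1], per_method[m2])
            if np.isnan(rho):
                logger.info(
                    "similarity: undefined correlation (%s, %s) on %s; skipped",
                    m1, m2, ds,
                )
                continue
            acc.loc[m1, m2] += rho
            acc.loc[m2, m1] += rho
            cnt.loc[m1, m2] += 1
            cnt.loc[m2, m1] += 1
    with np.errstate(invalid="ignore"):
        values = acc / cnt.replace(0, np.nan)
    for m in methods:
        values.loc[m, m] = 1.0
    return SimilarityMatrix(methods=tuple(methods), values=values)


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    n_nonzero: int
    statistic: float  # W+ = sum of signed ranks of positive differences
    method: str  # "exact" or "normal"
    degenerate: bool = False  # all paired differences were zero


def wilcoxon_greater(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """One-sided paired Wilcoxon signed-rank test of median(x) > median(y).

    Zero differences are discarded. The null distribution of W+ is
    enumerated exactly (sign-flip convolution over midranks, valid under
    ties) for up to ``exact_max_n`` non-zero pairs; beyond that a normal
    approximation with tie correction and continuity correction is used.
    If every difference is zero the result is p = 1, flagged degenerate.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(1.0, 0, 0.0, "exact", degenerate=True)

    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        # Doubled midranks are integers; convolve the sign-flip distribution.
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        threshold = int(np.rint(2 * w_plus))
        p = counts[threshold:].sum() / counts.sum()
        return WilcoxonResult(float(p), n, w_plus, "exact")

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return WilcoxonResult(float(norm.sf(z)), n, w_plus, "normal")


def compare_methods(
    auc_table: pd.DataFrame, m1: str, m2: str
) -> WilcoxonResult:
    """Paired one-sided Wilcoxon: does method m1 reach higher AUCs than m2?

    ``auc_table`` has columns method, dataset (or disease) and auc; the two
    methods are paired on the remaining key columns.
    """
    keys = [c for c in auc_table.columns if c not in ("method", "auc")]
    a = auc_table[auc_table["method"] == m1].set_index(keys)["auc"]
    b = auc_table[auc_table["method"] == m2].set_index(keys)["auc"]
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError(f"no shared evaluations between {m1!r} and {m2!r}")
    return wilcoxon_greater(a.loc[common].to_numpy(), b.loc[common].to_numpy())
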