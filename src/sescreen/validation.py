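"""Statistical, biological and topological validation of the screen.

Covers the hypergeometric enrichment of known adverse drugs in the
AS >= 0.5 selection, ROC/AUC over decreasing adjusted similarity, a
two-sample t comparison of AS distributions, the shared-side-effect
vocabulary overlap, and complete-linkage disease dendrograms on the
drug-disease similarity matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn import metrics as skm

from .io import SideEffectCatalog


@dataclass
class EnrichmentResult:
    """Hypergeometric upper-tail test of a selection against a property."""

    universe: int        # U: number of drugs in the catalog universe
    property_size: int   # K: drugs known to carry the property
    selection: int       # S: drugs selected by the screen
    intersection: int    # X: selected drugs carrying the property
    p_value: float


@dataclass
class ROCCurve:
    thresholds: np.ndarray   # decreasing AS values
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class TTestResult:
    t: float
    p_value: float
    mean_a: float
    mean_b: float
    degenerate: bool = False   # zero pooled variance


def hypergeometric_upper(universe: int, property_size: int, selection: int,
                         intersection: int) -> float:
    """P(X' >= X) for the overlap of a random selection with the property:

        p = sum_{i=X}^{S} C(K, i) C(U-K, S-i) / C(U, S)

    inclusive of i = X. Evaluated through the survival function of the
    hypergeometric distribution (log-space binomials; stable for U well
    beyond 1e5).
    """
    U, K, S, X = universe, property_size, selection, intersection
    if not (0 <= K <= U and 0 <= S <= U):
        raise ValueError(f"inconsistent counts: U={U}, K={K}, S={S}")
    if not 0 <= X <= min(K, S):
        raise ValueError(f"intersection X={X} outside [0, min(K={K}, S={S})]")
    return float(stats.hypergeom.sf(X - 1, U, K, S))


def enrichment(selected: Iterable[str], known: Iterable[str],
               universe: Iterable[str]) -> EnrichmentResult:
    """Convenience wrapper: restrict all sets to the drug universe and run
    the hypergeometric upper-tail test."""
    uni = set(universe)
    sel = set(selected) & uni
    prop = set(known) & uni
    x = len(sel & prop)
    return EnrichmentResult(len(uni), len(prop), len(sel), x,
                            hypergeometric_upper(len(uni), len(prop), len(sel), x))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC over a decreasing-similarity threshold sweep, with trapezoid AUC.

    Tied scores enter a threshold step together; the AUC equals the
    tie-corrected Mann-Whitney rank statistic. Requires at least one
    positive and one negative label.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("scores and labels differ in length")
    if y.min() == y.max():
        raise ValueError("labels contain a single class; ROC is undefined")
    fpr, tpr, thr = skm.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(skm.auc(fpr, tpr)))


def compare_as_distributions(group_a: Sequence[float], group_b: Sequence[float],
                             welch: bool = False) -> TTestResult:
    """Two-sample Student's t (pooled variance; Welch by flag), two-sided.

    Zero within-group variance is flagged degenerate: equal means give
    t = 0, p = 1; unequal means give an infinite-t sentinel with p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, float(a.mean()), float(b.mean()), True)
        t = math.copysign(math.inf, a.mean() - b.mean())
        return TTestResult(t, 0.0, float(a.mean()), float(b.mean()), True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       float(a.mean()), float(b.mean()))


def side_effect_overlap(reference_drugs: Iterable[str], candidate_drugs: Iterable[str],
                        catalog: SideEffectCatalog, exclude_term: str | None = None,
                        ) -> tuple[int, int, float]:
    """Fraction of the candidate drugs' side-effect vocabulary shared with
    the reference drugs' vocabulary, excluding the side effect under study.

    Returns (n_shared, n_candidate_total, fraction).
    """
    if not catalog.pairs:
        raise ValueError("empty side-effect catalog")
    ref = set(reference_drugs)
    cand = set(candidate_drugs)
    vocab_ref = {t for d, t in catalog.pairs if d in ref and t != exclude_term}
    vocab_cand = {t for d, t in catalog.pairs if d in cand and t != exclude_term}
    shared = len(vocab_ref & vocab_cand)
    total = len(vocab_cand)
    return shared, total, (shared / total) if total else 0.0


@dataclass
class DendrogramResult:
    linkage: np.ndarray
    labels: list[str]        # disease ids, row order of the linkage


def disease_dendrogram(as_matrix: pd.DataFrame,
                       drug_subset: Iterable[str] | None = None) -> DendrogramResult:
    """Complete-linkage clustering of the disease rows of an AS matrix.

    Each cell is turned into a dissimilarity 1 - AS (absent pairs impute to
    distance 1) and rows are compared by Euclidean distance before
    complete-linkage agglomeration. Column order does not matter.
    """
    mat = as_matrix
    if drug_subset is not None:
        cols = [c for c in mat.columns if c in set(drug_subset)]
        if not cols:
            raise ValueError("drug subset shares no column with the matrix")
        mat = mat[cols]
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 diseases (rows)")
    d = (1.0 - mat.sort_index(axis=1).to_numpy(dtype=float))
    d = np.nan_to_num(d, nan=1.0)
    link = hierarchy.linkage(pdist(d, metric="euclidean"), method="complete")
    return DendrogramResult(link, list(mat.index))


def compare_dendrograms(a: DendrogramResult, b: DendrogramResult,
                        n_clusters: int = 2) -> tuple[bool, float]:
    """(same leaf partition at an n-cluster cut, cophenetic correlation)
    for two dendrograms over the same diseases."""
    if a.labels != b.labels:
        raise ValueError("dendrograms cover different diseases")
    ca = hierarchy.fcluster(a.linkage, t=n_clusters, criterion="maxclust")
    cb = hierarchy.fcluster(b.linkage, t=n_clusters, criterion="maxclust")
    part_a = {frozenset(np.flatnonzero(ca == c)) for c in np.unique(ca)}
    part_b = {frozenset(np.flatnonzero(cb == c)) for c in np.unique(cb)}
    coph_a = hierarchy.cophenet(a.linkage)
    coph_b = hierarchy.cophenet(b.linkage)
    if np.std(coph_a) == 0.0 or np.std(coph_b) == 0.0:
        corr = 1.0 if np.allclose(coph_a, coph_b) else 0.0
    else:
        corr = float(np.corrcoef(coph_a, coph_b)[0, 1])
    return part_a == part_b, corr
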