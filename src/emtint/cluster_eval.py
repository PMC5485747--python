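"""Baker-Hubert gamma evaluation of sample grouping by phenotype.

The Baker-Hubert index compares every within-cluster pair distance against
every between-cluster pair distance: S+ counts comparisons where the
within distance is smaller, S- where it is larger (ties count to
neither), and the index is (S+ - S-)/(S+ + S-), ranging from -1 (samples
group against the labels) through 0 (no relation) to 1 (perfect
grouping).  Here the known phenotype vector plays the role of the cluster
assignment, so the index scores how well a normalization makes samples of
the same phenotype mutually closer than samples of opposite phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import pdist, squareform


@dataclass
class BHResult:
    """Concordant/disconcordant comparison counts and the resulting index."""

    s_plus: int
    s_minus: int
    index: float | None
    status: str = "ok"


def sample_distance(
    values: pd.DataFrame | np.ndarray, metric: str = "correlation",
    center_genes: bool = False,
) -> pd.DataFrame | np.ndarray:
    """Pairwise distances between sample columns of a genes x samples matrix.

    ``correlation`` is 1 - Pearson r; a constant column makes that
    undefined and raises, naming the sample.  ``center_genes`` subtracts
    each gene's mean first — the usual preliminary for sample-similarity
    analysis, since otherwise the shared baseline expression profile
    dominates every sample-sample correlation and masks group structure.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    arr = np.asarray(values, dtype=np.float64)
    if center_genes:
        arr = arr - arr.mean(axis=1, keepdims=True)
    if metric == "correlation":
        sds = arr.std(axis=0)
        bad = np.flatnonzero(sds == 0)
        if bad.size:
            names = (
                [values.columns[i] for i in bad]
                if isinstance(values, pd.DataFrame)
                else bad.tolist()
            )
            raise ValueError(f"constant sample column(s) {names[:5]}: correlation undefined")
    d = squareform(pdist(arr.T, metric=metric))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(d, index=values.columns, columns=values.columns)
    return d


def _within_between(d: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    dist = d[iu, ju]
    return dist[same], dist[~same]


def baker_hubert(d: pd.DataFrame | np.ndarray, labels: Sequence) -> BHResult:
    """Baker-Hubert index of a distance matrix against a label vector.

    Counts, over all (within-cluster pair, between-cluster pair)
    combinations, how often the within distance is strictly smaller (S+)
    or strictly larger (S-); tied comparisons contribute to neither.
    Uses sort-plus-binary-search counting, O(P log P) in the number of
    pair distances, and agrees exactly with exhaustive enumeration.
    Fewer than two clusters, or any cluster with fewer than two members,
    leaves the index undefined (None) with an explanatory status.
    """
    dm = np.asarray(d, dtype=np.float64)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    lab = np.asarray([str(v) for v in labels])
    if len(lab) != dm.shape[0]:
        raise ValueError("labels must match the distance matrix size")
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        return BHResult(0, 0, None, status="fewer than 2 clusters")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        return BHResult(0, 0, None, status=f"cluster(s) with <2 members: {small}")
    within, between = _within_between(dm, lab)
    between_sorted = np.sort(between)
    # for each within distance w: S+ gains #(b > w), S- gains #(b < w)
    s_plus = int((len(between_sorted) - np.searchsorted(between_sorted, within, side="right")).sum())
    s_minus = int(np.searchsorted(between_sorted, within, side="left").sum())
    total = s_plus + s_minus
    index = (s_plus - s_minus) / total if total > 0 else None
    status = "ok" if total > 0 else "all distance comparisons tied"
    return BHResult(s_plus, s_minus, index, status=status)


def baker_hubert_bruteforce(d: np.ndarray, labels: Sequence) -> BHResult:
    """Direct enumeration of the concordant/disconcordant quadruple rules.

    For every unordered pair {a, b} and every unordered pair {c, d}, a
    comparison is concordant when d(a,b) > d(c,d) with c,d co-clustered
    and a,b split (or the mirrored condition), disconcordant with the
    roles of the inequality reversed.  Independent oracle for
    :func:`baker_hubert`; quadratic in the number of pairs.
    """
    dm = np.asarray(d, dtype=np.float64)
    lab = np.asarray([str(v) for v in labels])
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        return BHResult(0, 0, None, status="fewer than 2 clusters")
    if (counts < 2).any():
        return BHResult(0, 0, None, status="cluster with <2 members")
    n = dm.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    s_plus = s_minus = 0
    for (a, b) in pairs:
        ab_same = lab[a] == lab[b]
        for (c, dd) in pairs:
            cd_same = lab[c] == lab[dd]
            if ab_same == cd_same:
                continue
            if dm[a, b] > dm[c, dd] and cd_same:
                s_plus += 1
            elif dm[a, b] < dm[c, dd] and ab_same:
                s_plus += 1
            elif dm[a, b] > dm[c, dd] and ab_same:
                s_minus += 1
            elif dm[a, b] < dm[c, dd] and cd_same:
                s_minus += 1
    # each (within, between) comparison is visited twice (ordered pair-of-pairs)
    assert s_plus % 2 == 0 and s_minus % 2 == 0
    s_plus //= 2
    s_minus //= 2
    total = s_plus + s_minus
    index = (s_plus - s_minus) / total if total > 0 else None
    status = "ok" if total > 0 else "all distance comparisons tied"
    return BHResult(s_plus, s_minus, index, status=status)


def evaluate_grouping(
    values_per_method: Mapping[str, pd.DataFrame],
    phenotype: Sequence,
    metric: str = "correlation",
    center_genes: bool = True,
) -> pd.DataFrame:
    """Baker-Hubert index of every normalization scheme against the phenotype.

    Genes are mean-centered before computing sample distances (the
    standard move for sample-similarity analysis; schemes that retain the
    per-gene baseline would otherwise have their group separation
    compressed by the baseline profile all samples share).  Returns a
    table (one row per method) of S+, S- and the index — the shape of a
    normalization-comparison summary.
    """
    rows = []
    for method, values in values_per_method.items():
        d = sample_distance(values, metric=metric, center_genes=center_genes)
        res = baker_hubert(d, phenotype)
        rows.append(
            {
                "method": method,
                "s_plus": res.s_plus,
                "s_minus": res.s_minus,
                "bh_index": res.index,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows).set_index("method")


def dendrogram_newick(values: pd.DataFrame, metric: str = "correlation") -> str:
    """Average-linkage dendrogram of samples as a Newick string (inspection aid)."""
    d = pdist(np.asarray(values, dtype=np.float64).T, metric=metric)
    tree = to_tree(average(d))
    names = list(values.columns)

    def walk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"
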