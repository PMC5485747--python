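"""Differential expression between phenotypes and consensus rank aggregation.

Per normalization scheme: equal-variance two-sample t-test per gene
(epithelial vs mesenchymal), Bonferroni and Benjamini-Hochberg adjustment,
log2 fold change as the difference of group means on the normalized scale,
and raw-p ranking.  Across schemes: Spearman concordance of the test
statistics, per-gene average rank as the consensus ordering, and candidate
selection by consensus order subject to fold-change and FDR filters.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from emtint.io import EPITHELIAL, MESENCHYMAL

DEFAULT_FILTER_METHODS = ("SVA", "QN_SVA", "MCtr")


def _group_masks(phenotype: Sequence) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray([str(v) for v in phenotype])
    epi = labels == EPITHELIAL
    mes = labels == MESENCHYMAL
    if not epi.any() or not mes.any():
        raise ValueError("both phenotype groups must be non-empty")
    return epi, mes


def two_sample_ttest(
    values: pd.DataFrame | np.ndarray, phenotype: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance t and two-sided p per gene, epithelial minus mesenchymal.

    Genes with zero pooled variance get ``t = NaN, p = NaN`` (undefined
    test) with a warning; downstream ranking pushes them last.
    """
    arr = np.asarray(values, dtype=np.float64)
    epi, mes = _group_masks(phenotype)
    if epi.sum() < 2 or mes.sum() < 2:
        raise ValueError("each phenotype group needs at least 2 samples")
    a, b = arr[:, epi], arr[:, mes]
    n1, n2 = a.shape[1], b.shape[1]
    ss1 = a.var(axis=1, ddof=1) * (n1 - 1)
    ss2 = b.var(axis=1, ddof=1) * (n2 - 1)
    pooled = (ss1 + ss2) / (n1 + n2 - 2)
    degenerate = pooled == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have zero pooled variance; "
            "p reported as NaN and ranked last",
            stacklevel=2,
        )
        t = t.copy()
        p = p.copy()
        t[degenerate] = np.nan
        p[degenerate] = np.nan
    return t, p


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Family-wise adjusted p: ``min(1, p * m)`` elementwise."""
    p = np.asarray(p, dtype=np.float64)
    if m is None:
        m = len(p)
    if m < np.sum(~np.isnan(p)):
        raise ValueError("m must cover every p-value considered")
    return np.minimum(1.0, p * m)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as NaN."""
    p = np.asarray(p, dtype=np.float64)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def fold_change(
    values: pd.DataFrame | np.ndarray, phenotype: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (log2 fold change, linear fold change), epithelial minus mesenchymal.

    Values are treated as log2-scale, so the linear fold change is
    ``2 ** log2FC``; the conventional "absolute fold change > c" filter means
    linear FC > c or < 1/c.
    """
    arr = np.asarray(values, dtype=np.float64)
    epi, mes = _group_masks(phenotype)
    log2fc = arr[:, epi].mean(axis=1) - arr[:, mes].mean(axis=1)
    return log2fc, 2.0 ** log2fc


def rank_by_pvalue(p: np.ndarray) -> np.ndarray:
    """Ascending ranks (1 = smallest p); ties averaged; NaN ranked last."""
    p = np.asarray(p, dtype=np.float64)
    ranks = np.empty(len(p), dtype=np.float64)
    ok = ~np.isnan(p)
    ranks[ok] = stats.rankdata(p[ok], method="average")
    n_nan = int((~ok).sum())
    if n_nan:
        # NaNs share the average of the trailing rank positions
        ranks[~ok] = ok.sum() + (n_nan + 1) / 2.0
    return ranks


def differential_expression(
    values: pd.DataFrame, phenotype: Sequence, collapse_replicates: bool = False,
    replicate_of: Sequence | None = None,
) -> pd.DataFrame:
    """Full per-gene DE table for one normalized matrix.

    Columns: ``t_statistic, p_value, bonferroni_p, fdr_q, log2_fold_change,
    fold_change, rank``.  Replicates are treated as independent
    observations by default; ``collapse_replicates=True`` averages each
    replicate group (parent plus its replicates) into one column first.
    """
    if collapse_replicates:
        if replicate_of is None:
            raise ValueError("collapse_replicates requires replicate_of")
        values, phenotype = _collapse_replicates(values, phenotype, replicate_of)
    t, p = two_sample_ttest(values, phenotype)
    log2fc, fc = fold_change(values, phenotype)
    out = pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "bonferroni_p": bonferroni(p, len(p)),
            "fdr_q": bh_fdr(p),
            "log2_fold_change": log2fc,
            "fold_change": fc,
            "rank": rank_by_pvalue(p),
        },
        index=values.index if isinstance(values, pd.DataFrame) else None,
    )
    return out


def _collapse_replicates(values: pd.DataFrame, phenotype: Sequence, replicate_of: Sequence):
    parents = []
    samples = list(values.columns)
    pheno = dict(zip(samples, [str(v) for v in phenotype]))
    rep = dict(zip(samples, list(replicate_of)))
    groups: dict[str, list[str]] = {}
    for s in samples:
        r = rep.get(s)
        parent = s if (r is None or (isinstance(r, float) and np.isnan(r)) or r == "") else r
        groups.setdefault(parent, []).append(s)
    cols = {}
    labels = []
    for parent, members in groups.items():
        cols[parent] = values[members].mean(axis=1)
        labels.append(pheno[parent])
        parents.append(parent)
    collapsed = pd.DataFrame(cols)[parents]
    return collapsed, labels


def concordance(
    stat_vectors: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (and two-sided p) between per-method statistics.

    A constant vector has undefined rank correlation: the affected entries
    are reported as NaN.
    """
    names = list(stat_vectors)
    n = None
    for name in names:
        v = np.asarray(stat_vectors[name], dtype=np.float64)
        if n is None:
            n = len(v)
        elif len(v) != n:
            raise ValueError("all statistic vectors must have equal length")
    if n is None or n < 3:
        raise ValueError("need vectors of length >= 3")
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    np.fill_diagonal(pval.values, 0.0)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            x = np.asarray(stat_vectors[a], dtype=np.float64)
            y = np.asarray(stat_vectors[b], dtype=np.float64)
            if np.all(x == x[0]) or np.all(y == y[0]):
                r, pv = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, pv = stats.spearmanr(x, y)
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = pv
    return rho, pval


def consensus_rank(rank_vectors: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Average the per-method raw-p ranks into a consensus ordering.

    Returns a DataFrame indexed by gene with each method's rank,
    ``mean_rank`` and ``final_order`` (1 = best); mean-rank ties break by
    lexicographic gene id.
    """
    names = list(rank_vectors)
    if not names:
        raise ValueError("no rank vectors supplied")
    universe = None
    aligned = {}
    for name in names:
        s = pd.Series(rank_vectors[name])
        idx = frozenset(s.index)
        if universe is None:
            universe = idx
        elif idx != universe:
            raise ValueError(f"rank vector {name!r} covers a different gene universe")
        aligned[name] = s
    table = pd.DataFrame(aligned)
    table = table.sort_index()
    table["mean_rank"] = table[names].mean(axis=1)
    order = table.sort_values(["mean_rank"], kind="stable").index
    table.loc[order, "final_order"] = np.arange(1, len(table) + 1)
    table["final_order"] = table["final_order"].astype(int)
    return table


def select_candidates(
    consensus: pd.DataFrame,
    de: Mapping[str, pd.DataFrame],
    top_n: int = 200,
    fc_threshold: float = 1.2,
    fdr_threshold: float = 0.005,
    filter_methods: Sequence[str] = DEFAULT_FILTER_METHODS,
) -> list[str]:
    """Candidate genes: consensus order, filtered by |FC| and FDR in every filter method.

    A gene qualifies when, in each of ``filter_methods``, its linear fold
    change exceeds ``fc_threshold`` (or falls below its reciprocal) and its
    BH q-value is below ``fdr_threshold``.  Qualifying genes are taken in
    consensus order and truncated to ``top_n``; a warning is issued when
    fewer qualify.
    """
    missing = [m for m in filter_methods if m not in de]
    if missing:
        raise ValueError(f"DE results missing for filter methods: {missing}")
    passing = pd.Series(True, index=consensus.index)
    for method in filter_methods:
        table = de[method].reindex(consensus.index)
        fc = table["fold_change"]
        fc_ok = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
        fdr_ok = table["fdr_q"] < fdr_threshold
        passing &= fc_ok.fillna(False) & fdr_ok.fillna(False)
    ordered = consensus.sort_values("final_order").index
    selected = [g for g in ordered if passing[g]][:top_n]
    if len(selected) < top_n:
        warnings.warn(
            f"only {len(selected)} genes pass the fold-change/FDR filters "
            f"(requested top {top_n})",
            stacklevel=2,
        )
    return selected
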