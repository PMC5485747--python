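"""Weighted co-expression modules among candidate genes.

After regressing the phenotype out of each gene (so modules reflect
co-variation beyond the epithelial/mesenchymal contrast), an unsigned
soft-threshold adjacency ``a_ij = |corr(e_i, e_j)|^beta`` is built, beta
chosen for approximate scale-free connectivity; the adjacency is turned
into a topological-overlap similarity (TOM), whose dissimilarity feeds
average-linkage clustering with an adaptive cut and a minimum module
size.  Each module is summarized by its eigengene, the first principal
component of the standardized module submatrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from emtint.normalization import _phenotype_design

DEFAULT_BETA_GRID = tuple(np.arange(1.0, 12.5, 0.5))


def regress_out_phenotype(
    values: pd.DataFrame | np.ndarray, phenotype: Sequence
) -> pd.DataFrame | np.ndarray:
    """Residuals of each gene after least squares on intercept + phenotype.

    Equivalent to subtracting each phenotype group's mean from its samples
    (within-group centering), for balanced or unbalanced groups alike.
    """
    arr = np.asarray(values, dtype=np.float64)
    design = _phenotype_design(phenotype)  # raises if one class is empty
    beta, *_ = np.linalg.lstsq(design, arr.T, rcond=None)
    resid = (arr.T - design @ beta).T
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(resid, index=values.index, columns=values.columns)
    return resid


def adjacency(residuals: pd.DataFrame | np.ndarray, beta: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``|corr|^beta`` between gene rows."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    arr = np.asarray(residuals, dtype=np.float64)
    sds = arr.std(axis=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        names = (
            [residuals.index[i] for i in bad]
            if isinstance(residuals, pd.DataFrame)
            else bad.tolist()
        )
        raise ValueError(f"zero-variance gene(s) {names[:5]}: correlation undefined")
    corr = np.corrcoef(arr)
    np.clip(corr, -1.0, 1.0, out=corr)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)  # connectivity sums exclude self
    return adj


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Per-gene connectivity k_i = sum_{j != i} a_ij (diagonal excluded)."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit of a connectivity distribution.

    Bins log10(k) into equal-width bins, regresses log10 of the occupied
    bins' frequency on log10 of their mean connectivity, and returns
    ``(signed_r2, slope)`` where the R-squared is negated when the slope
    is positive (a scale-free network has a decreasing degree law).
    """
    k = np.asarray(k, dtype=np.float64)
    k = k[k > 0]
    if len(k) < 3 or np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity distribution; cannot assess scale-freeness")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.allclose(xs, xs[0]):
        raise ValueError("too few occupied connectivity bins for a scale-free fit")
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = float(((ys - fitted) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    signed = r2 * (-np.sign(slope)) if slope != 0 else 0.0
    return float(signed), float(slope)


def pick_beta(
    residuals: pd.DataFrame | np.ndarray,
    grid: Sequence[float] = DEFAULT_BETA_GRID,
    target_r2: float = 0.8,
    rule: str = "threshold",
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power from a scale-free fit over a beta grid.

    ``rule="threshold"`` takes the smallest beta whose signed R-squared
    reaches ``target_r2``, falling back to the argmax when none does;
    ``rule="argmax"`` always takes the best-fitting beta.  The default
    grid runs 1 to 12 in half steps.  Returns the chosen beta and the
    full fit table (beta, signed R2, slope, mean connectivity).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("beta grid must be nonempty")
    if rule not in ("threshold", "argmax"):
        raise ValueError("rule must be 'threshold' or 'argmax'")
    arr = np.asarray(residuals, dtype=np.float64)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 genes to assess a degree distribution")
    rows = []
    for beta in grid:
        adj = adjacency(arr, beta)
        k = connectivity(adj)
        signed_r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {"beta": beta, "signed_r2": signed_r2, "slope": slope, "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    reaching = table[table["signed_r2"] >= target_r2]
    if rule == "threshold" and not reaching.empty:
        beta = float(reaching.iloc[0]["beta"])
    else:
        beta = float(table.loc[table["signed_r2"].idxmax(), "beta"])
    return beta, table


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an unsigned adjacency.

    ``TOM_ij = (sum_{k != i,j} a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with connectivity ``k_i`` excluding the diagonal; the diagonal of the
    result is 1.  A zero denominator (only possible for fully isolated
    node pairs) yields TOM = 0 with a warning.
    """
    a = np.asarray(adj, dtype=np.float64).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # entry ij sums a_ik a_kj over all k (diag zeroed, so k != i, j handled)
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    out = np.empty_like(a)
    zero = denom == 0
    if zero.any():
        warnings.warn("zero TOM denominator; overlap reported as 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, 0.0, numer / np.where(zero, 1.0, denom))
    np.fill_diagonal(out, 1.0)
    return out


def diss_tom(adj: np.ndarray) -> np.ndarray:
    """1 - TOM, the clustering dissimilarity."""
    return 1.0 - tom(adj)


@dataclass
class ModuleAssignment:
    """Gene-to-module labels (0 = unassigned) and per-module eigengenes."""

    labels: pd.Series  # gene -> int
    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    variance_explained: dict[int, float]

    @property
    def n_modules(self) -> int:
        return int((pd.unique(self.labels) != 0).sum())

    def module_genes(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(
    disstom: np.ndarray,
    min_module_size: int = 15,
    reassign: bool = True,
    max_cut_height: float = 0.95,
) -> np.ndarray:
    """Cut an average-linkage dendrogram of dissTOM into modules.

    Scans the dendrogram's merge heights up to ``max_cut_height``, keeps
    at each height the clusters with at least ``min_module_size``
    members, and adopts the height yielding the most qualifying modules
    (ties resolved toward the higher height, so late-joining members of
    a module are still absorbed before the count drops).  The cap is in
    dissTOM units: clusters cohering only at topological overlap below
    ``1 - max_cut_height`` never qualify, which is what keeps a
    structure-free input from being reported as one giant root module.
    Genes outside qualifying clusters are labeled 0; one reassignment
    pass then attaches each unassigned gene to the module with the
    smallest average dissimilarity, provided that average falls below
    the module's internal median dissimilarity.  Labels are renumbered
    1.. by decreasing module size.
    """
    d = np.asarray(disstom, dtype=np.float64)
    n = d.shape[0]
    if n < min_module_size:
        return np.zeros(n, dtype=int)
    link = average(squareform(d, checks=False))
    heights = np.unique(link[:, 2])
    heights = heights[heights <= max_cut_height]
    best_height = None
    best_count = -1
    eps = 1e-10
    for h in heights:
        flat = fcluster(link, t=h + eps, criterion="distance")
        count = int((np.bincount(flat)[1:] >= min_module_size).sum())
        if count >= best_count:
            best_count = count
            best_height = h + eps
    if best_count <= 0:
        return np.zeros(n, dtype=int)
    flat = fcluster(link, t=best_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(flat).value_counts()
    qualifying = [c for c, s in sizes.items() if s >= min_module_size]
    # stable module numbering: by decreasing size, then smallest member index
    qualifying.sort(key=lambda c: (-sizes[c], int(np.flatnonzero(flat == c)[0])))
    for new, c in enumerate(qualifying, start=1):
        labels[flat == c] = new
    if reassign:
        labels = _reassign_pass(d, labels)
    return labels


def _reassign_pass(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Attach unassigned genes to their nearest module when close enough."""
    out = labels.copy()
    modules = sorted(set(labels) - {0})
    if not modules:
        return out
    medians = {}
    for m in modules:
        idx = np.flatnonzero(labels == m)
        sub = d[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        medians[m] = float(np.median(sub[iu])) if iu[0].size else 0.0
    for i in np.flatnonzero(labels == 0):
        dists = {m: float(d[i, labels == m].mean()) for m in modules}
        best = min(dists, key=lambda m: (dists[m], m))
        if dists[best] < medians[best]:
            out[i] = best
    return out


def module_eigengene(
    values: pd.DataFrame, labels: Sequence[int]
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component of each module's standardized submatrix.

    Gene rows are z-scored, the leading right singular vector over samples
    is the eigengene (unit norm), its sign oriented to correlate
    positively with the module's mean standardized profile.  Returns the
    eigengene table (modules x samples) and per-module fraction of
    variance explained.
    """
    lab = np.asarray(labels, dtype=int)
    if len(lab) != values.shape[0]:
        raise ValueError("labels must align with gene rows")
    eigengenes = {}
    varexp = {}
    for m in sorted(set(lab) - {0}):
        sub = np.asarray(values, dtype=np.float64)[lab == m]
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mean) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eg = vt[0]
        profile = z.mean(axis=0)
        if np.dot(eg, profile) < 0:
            eg = -eg
        eigengenes[m] = eg
        varexp[m] = float(s[0] ** 2 / (s ** 2).sum()) if s.size else 0.0
    table = pd.DataFrame.from_dict(eigengenes, orient="index", columns=values.columns)
    table.index.name = "module"
    return table, varexp


class TomModuleDetector(ClusterMixin, BaseEstimator):
    """Scikit-learn-style clusterer: genes (rows of X) into TOM modules.

    Parameters
    ----------
    beta : float or "auto"
        Soft-threshold power; ``"auto"`` selects it by the scale-free fit
        over ``beta_grid``.
    beta_grid : sequence of float or None
        Candidate powers (default 1..12 in half steps).
    target_r2 : float
        Signed scale-free R-squared a power must reach under the
        ``"threshold"`` rule.
    beta_rule : {"threshold", "argmax"}
        How to choose beta from the fit table.
    min_module_size : int
        Smallest reportable module.
    max_cut_height : float
        Highest dendrogram cut considered, in dissTOM units.

    ``fit(X)`` expects ``X`` of shape (n_genes, n_samples) — typically the
    phenotype-residual matrix.  Fitted attributes: ``beta_``,
    ``fit_table_``, ``tom_``, ``labels_`` (0 = unassigned), ``n_modules_``.
    """

    def __init__(self, beta="auto", beta_grid=None, target_r2: float = 0.8,
                 beta_rule: str = "threshold", min_module_size: int = 15,
                 max_cut_height: float = 0.95):
        self.beta = beta
        self.beta_grid = beta_grid
        self.target_r2 = target_r2
        self.beta_rule = beta_rule
        self.min_module_size = min_module_size
        self.max_cut_height = max_cut_height

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("X must be a 2-D genes x samples matrix")
        grid = DEFAULT_BETA_GRID if self.beta_grid is None else self.beta_grid
        if self.beta == "auto":
            self.beta_, self.fit_table_ = pick_beta(
                arr, grid=grid, target_r2=self.target_r2, rule=self.beta_rule
            )
        else:
            self.beta_ = float(self.beta)
            self.fit_table_ = None
        adj = adjacency(arr, self.beta_)
        self.tom_ = tom(adj)
        self.labels_ = detect_modules(
            1.0 - self.tom_, min_module_size=self.min_module_size,
            max_cut_height=self.max_cut_height,
        )
        self.n_modules_ = int(len(set(self.labels_) - {0}))
        return self

    def assignment(self, values: pd.DataFrame) -> ModuleAssignment:
        """Package labels and eigengenes (computed on ``values``) together."""
        labels = pd.Series(self.labels_, index=values.index, name="module")
        eigengenes, varexp = module_eigengene(values, self.labels_)
        return ModuleAssignment(labels=labels, eigengenes=eigengenes,
                                variance_explained=varexp)
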