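"""Four cross-study correction schemes: QN, SVA, QN+SVA and MCtr.

Quantile normalization (QN) forces every sample onto one reference
distribution (the row means of the column-sorted matrix).  Surrogate
variable analysis (SVA) estimates latent confounders as the leading
singular vectors of the expression matrix residualized on the phenotype,
then removes them by regression while protecting the phenotype term.
MCtr standardizes each sample column to unit variance and then centers
every gene to median zero, independently within each study, before
merging.  QN+SVA composes the first two on the merged matrix.

The transformers follow the scikit-learn estimator API and operate on
``(n_samples, n_features)`` arrays; the module-level functions wrap them
for the genes x samples DataFrames used elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from emtint.io import EPITHELIAL, IntegratedMatrix, SampleMetadata, intersect_and_merge

METHODS = ("NONE", "QN", "SVA", "QN_SVA", "MCtr")


def _phenotype_design(phenotype: Sequence) -> np.ndarray:
    """Intercept + 0/1 phenotype column (epithelial = 1)."""
    vals = list(phenotype)
    labels = {str(v) for v in vals}
    if labels <= {EPITHELIAL, "mesenchymal"}:
        p = np.asarray([1.0 if str(v) == EPITHELIAL else 0.0 for v in vals])
    else:
        p = np.asarray(vals, dtype=float)
    if len(np.unique(p)) < 2:
        raise ValueError("both phenotype classes must be present")
    return np.column_stack([np.ones(len(p)), p])


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Map every sample's value distribution onto a common reference.

    ``fit`` learns the reference distribution as the mean of the per-sample
    sorted value vectors; ``transform`` replaces each sample's values by
    the reference values at the corresponding ranks.  Tied values receive
    the mean of the reference values at the ranks they occupy, so the
    operation is idempotent and rank-preserving within each sample.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, fitted for {self.n_features_in_}"
            )
        ref = self.reference_
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = _map_to_reference(X[i], ref)
        return out


def _map_to_reference(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Assign ref values by rank; ties get the mean of their occupied ranks."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    out_sorted = ref.astype(np.float64).copy()
    # tie groups in the sorted sample share the mean reference value
    boundaries = np.flatnonzero(np.diff(xs) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(xs)]])
    for a, b in zip(starts, ends):
        if b - a > 1:
            out_sorted[a:b] = ref[a:b].mean()
    out = np.empty_like(out_sorted)
    out[order] = out_sorted
    return out


def quantile_normalize(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Quantile-normalize the columns of a genes x samples matrix."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one column")
    if np.isnan(arr).any():
        raise ValueError("missing values not allowed in quantile normalization")
    normalized = QuantileNormalizer().fit_transform(arr.T).T
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(normalized, index=values.index, columns=values.columns)
    return normalized


@dataclass
class SurrogateVariables:
    """Estimated latent confounders in sample space."""

    k: int
    sv_matrix: np.ndarray  # (n_samples, k), orthonormal columns
    singular_values: np.ndarray  # descending, full residual spectrum


class SurrogateVariableCorrector(TransformerMixin, BaseEstimator):
    """Estimate and remove surrogate variables, protecting the phenotype.

    Parameters
    ----------
    k : int or "auto"
        Number of surrogate variables.  ``"auto"`` selects k by permutation
        parallel analysis: each gene's residual vector is permuted across
        samples ``n_permutations`` times, and leading components are kept
        while their singular value exceeds the ``percentile``-th percentile
        of the permuted singular values at the same position (stopping at
        the first failure).
    n_permutations : int
        Number of row permutations for parallel analysis.
    percentile : float
        Percentile of the permuted singular-value null used as threshold.
    random_state : int or None
        Seed for the permutation draws.

    After ``fit(X, y)`` (X of shape ``(n_samples, n_genes)``, y the
    phenotype labels), ``transform(X)`` subtracts only the fitted
    surrogate-variable component of each gene's least-squares fit on
    [intercept, phenotype, SVs]; intercept and phenotype contributions are
    retained.
    """

    def __init__(self, k="auto", n_permutations: int = 20, percentile: float = 95.0,
                 random_state=None):
        self.k = k
        self.n_permutations = n_permutations
        self.percentile = percentile
        self.random_state = random_state

    def fit(self, X, y=None, covariates=None):
        if y is None:
            raise ValueError("phenotype labels y are required to protect the signal")
        X = check_array(X, dtype=np.float64)
        n_samples = X.shape[0]
        design = _phenotype_design(y)
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
            if cov.shape[0] != n_samples:
                cov = cov.T
            if cov.shape[0] != n_samples:
                raise ValueError("covariates must align with samples")
            design = np.column_stack([design, cov])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise ValueError("known covariates are collinear with the phenotype design")
        if self.k != "auto":
            k_req = int(self.k)
            if k_req < 0:
                raise ValueError("k must be nonnegative")
            if k_req >= n_samples - 2:
                raise ValueError(f"k={k_req} must be < n_samples - 2 = {n_samples - 2}")
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        resid = X - design @ beta
        # sample-space singular vectors of the residual matrix
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        self.singular_values_ = s
        if not np.any(s > 1e-10):
            if self.k != "auto" and int(self.k) > 0:
                raise ValueError("residual matrix has zero variance; no SVs estimable")
            k = 0
        elif self.k == "auto":
            k = self._parallel_analysis_k(resid, s, design)
        else:
            k = int(self.k)
        self.k_ = k
        self.surrogate_variables_ = u[:, :k]
        full_design = np.column_stack([design, self.surrogate_variables_])
        rank = np.linalg.matrix_rank(full_design)
        if rank < full_design.shape[1]:
            raise ValueError("design matrix with SVs is rank-deficient")
        coef, *_ = np.linalg.lstsq(full_design, X, rcond=None)
        self.sv_coef_ = coef[design.shape[1]:, :]  # (k, n_genes)
        self.n_features_in_ = X.shape[1]
        return self

    def _parallel_analysis_k(self, resid: np.ndarray, s: np.ndarray,
                             design: np.ndarray) -> int:
        rng = np.random.default_rng(self.random_state)
        n_samples, n_genes = resid.shape
        n_keep = len(s)
        # Compare variance *fractions*, not raw singular values: the
        # observed residual spectrum is rank-reduced by the design
        # projection, so permuted draws must be re-residualized, and raw
        # scales are then incomparable while sv^2 / sum(sv^2) is not.
        proj = np.eye(n_samples) - design @ np.linalg.pinv(design)
        obs_frac = s ** 2 / np.sum(s ** 2)
        perm_frac = np.empty((self.n_permutations, n_keep))
        for b in range(self.n_permutations):
            permuted = resid.copy()
            # permute each gene's residuals independently across samples
            for j in range(n_genes):
                permuted[:, j] = permuted[rng.permutation(n_samples), j]
            permuted = proj @ permuted
            ps = np.linalg.svd(permuted, compute_uv=False)[:n_keep]
            perm_frac[b] = ps ** 2 / np.sum(ps ** 2)
        thresholds = np.percentile(perm_frac, self.percentile, axis=0)
        k = 0
        for j in range(min(n_samples - 2, n_keep)):
            if obs_frac[j] > thresholds[j]:
                k += 1
            else:
                break
        return k

    def transform(self, X):
        check_is_fitted(self, "surrogate_variables_")
        X = check_array(X, dtype=np.float64)
        if X.shape[0] != self.surrogate_variables_.shape[0]:
            raise ValueError("transform requires the samples the corrector was fitted on")
        if self.k_ == 0:
            return X
        return X - self.surrogate_variables_ @ self.sv_coef_

    def surrogate_variables(self) -> SurrogateVariables:
        check_is_fitted(self, "surrogate_variables_")
        return SurrogateVariables(
            k=self.k_,
            sv_matrix=self.surrogate_variables_,
            singular_values=self.singular_values_,
        )


def estimate_surrogate_variables(
    values: pd.DataFrame | np.ndarray,
    phenotype: Sequence,
    k="auto",
    n_permutations: int = 20,
    percentile: float = 95.0,
    random_state=None,
    covariates=None,
) -> SurrogateVariables:
    """Surrogate variables of a genes x samples matrix given phenotype labels.

    ``covariates`` optionally supplies known confounders (samples x q); the
    residual matrix is then formed after removing intercept, phenotype and
    covariate fits, so the SVs capture only the remaining hidden structure.
    """
    arr = np.asarray(values, dtype=np.float64)
    corr = SurrogateVariableCorrector(
        k=k, n_permutations=n_permutations, percentile=percentile, random_state=random_state
    ).fit(arr.T, y=list(phenotype), covariates=covariates)
    return corr.surrogate_variables()


def regress_out_svs(
    values: pd.DataFrame | np.ndarray,
    phenotype: Sequence,
    svs: SurrogateVariables,
) -> pd.DataFrame | np.ndarray:
    """Remove only the SV component of each gene's fit on [1, phenotype, SVs]."""
    arr = np.asarray(values, dtype=np.float64)
    if svs.k == 0:
        out = arr.copy()
    else:
        X = arr.T  # samples x genes
        if X.shape[0] != svs.sv_matrix.shape[0]:
            raise ValueError("SVs were estimated on a different number of samples")
        design = np.column_stack([_phenotype_design(phenotype), svs.sv_matrix])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "design matrix [intercept, phenotype, SVs] is rank-deficient; "
                "an SV is collinear with the phenotype/intercept columns"
            )
        coef, *_ = np.linalg.lstsq(design, X, rcond=None)
        sv_part = svs.sv_matrix @ coef[2:, :]
        out = (X - sv_part).T
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


class StudywiseMedianCenterScaler(TransformerMixin, BaseEstimator):
    """Column-standardized median centering, applied per study.

    Within each study block, sample columns are centered and scaled to unit
    standard deviation (n-1 denominator) and gene rows are then shifted to
    median zero.  ``order=("median_center", "standardize")`` swaps the two
    steps for sensitivity analysis.  Stateless: ``transform`` recomputes on
    the data it is given; ``studies`` passes per-sample study labels (rows
    of X are samples), ``None`` treats X as one study.
    """

    def __init__(self, order: tuple[str, str] = ("standardize", "median_center")):
        self.order = order

    def fit(self, X, y=None, studies=None):
        X = check_array(X, dtype=np.float64)
        if set(self.order) != {"standardize", "median_center"}:
            raise ValueError("order must be a permutation of standardize/median_center")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, studies=None):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=np.float64)
        if studies is None:
            studies = np.zeros(X.shape[0])
        studies = np.asarray(studies)
        out = np.empty_like(X)
        for label in pd.unique(studies):
            mask = studies == label
            out[mask] = self._one_study(X[mask])
        return out

    def fit_transform(self, X, y=None, studies=None):
        return self.fit(X, y, studies=studies).transform(X, studies=studies)

    def _one_study(self, block: np.ndarray) -> np.ndarray:
        # block: samples x genes for one study
        if block.shape[0] < 2:
            raise ValueError("each study needs at least 2 samples for standardization")
        work = block.copy()
        for step in self.order:
            if step == "standardize":
                mean = work.mean(axis=1, keepdims=True)
                sd = work.std(axis=1, ddof=1, keepdims=True)
                zero = np.flatnonzero(sd.ravel() == 0)
                if zero.size:
                    raise ValueError(
                        f"zero-variance sample column(s) at study positions {zero.tolist()}"
                    )
                work = (work - mean) / sd
            else:
                work = work - np.median(work, axis=0, keepdims=True)
        return work


def median_center_standardize(
    study_values: pd.DataFrame | np.ndarray,
    order: tuple[str, str] = ("standardize", "median_center"),
) -> pd.DataFrame | np.ndarray:
    """Apply MCtr to one study's genes x samples matrix."""
    arr = np.asarray(study_values, dtype=np.float64)
    if arr.shape[1] < 2:
        raise ValueError("MCtr needs at least 2 samples")
    out = StudywiseMedianCenterScaler(order=order).fit_transform(arr.T).T
    if isinstance(study_values, pd.DataFrame):
        return pd.DataFrame(out, index=study_values.index, columns=study_values.columns)
    return out


@dataclass
class NormalizedMatrix:
    """A normalization scheme's output, aligned to the integrated matrix."""

    method: str
    values: pd.DataFrame
    surrogate_variables: SurrogateVariables | None = None


def normalize(
    data,
    method: str,
    metadata: SampleMetadata | None = None,
    k="auto",
    random_state=None,
    mctr_order: tuple[str, str] = ("standardize", "median_center"),
) -> NormalizedMatrix:
    """Dispatch one of the correction schemes.

    ``data`` is either an :class:`IntegratedMatrix` or a list of
    :class:`~emtint.io.ExpressionStudy` (with ``metadata``).  QN, SVA and
    QN+SVA operate on the merged matrix; MCtr processes each study
    independently and merges afterwards.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    if isinstance(data, IntegratedMatrix):
        integrated = data
        studies = None
        metadata = integrated.metadata
    else:
        studies = list(data)
        if metadata is None:
            raise ValueError("metadata is required when passing a study list")
        integrated = None

    def merged() -> IntegratedMatrix:
        nonlocal integrated
        if integrated is None:
            integrated = intersect_and_merge(studies, metadata)
        return integrated

    if method == "NONE":
        m = merged()
        return NormalizedMatrix(method=method, values=m.values.copy())
    if method == "QN":
        m = merged()
        return NormalizedMatrix(method=method, values=quantile_normalize(m.values))
    if method in ("SVA", "QN_SVA"):
        m = merged()
        values = m.values
        if method == "QN_SVA":
            values = quantile_normalize(values)
        phenotype = m.phenotype
        svs = estimate_surrogate_variables(
            values, phenotype, k=k, random_state=random_state
        )
        corrected = regress_out_svs(values, phenotype, svs)
        return NormalizedMatrix(method=method, values=corrected, surrogate_variables=svs)
    # MCtr: per-study processing, then merge over the common genes
    if studies is not None:
        processed = [
            type(s)(study_id=s.study_id, platform_id=s.platform_id,
                    values=median_center_standardize(s.values, order=mctr_order))
            for s in studies
        ]
        m = intersect_and_merge(processed, metadata)
        return NormalizedMatrix(method=method, values=m.values)
    m = merged()
    study_labels = m.study
    blocks = []
    for label in pd.unique(study_labels.to_numpy()):
        cols = [s for s in m.samples if study_labels[s] == label]
        blocks.append(median_center_standardize(m.values[cols], order=mctr_order))
    values = pd.concat(blocks, axis=1)[m.samples]
    return NormalizedMatrix(method=method, values=values)
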