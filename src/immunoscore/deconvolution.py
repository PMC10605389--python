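"""Immune-cell fraction imputation by signature regression (CIBERSORT core).

A bulk mixture is regressed on a signature matrix of reference cell-type
profiles with linear nu-support-vector regression: the mixture is z-scored
over the shared genes and the signature is standardized as a whole matrix
(one mean and sd over all entries, which preserves convex mixing weights),
an SVR is fitted for each ``nu`` in a small grid, the fit with the lowest
reconstruction RMSE is kept, negative coefficients are truncated at zero
and the remainder renormalized to proportions summing to one.  An optional permutation test shuffles the
mixture across genes to calibrate the significance of the fit correlation.

Quantile normalization (the classic microarray default) is not applied:
the expected input is RNA-seq TPM, for which it is disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from sklearn.exceptions import ConvergenceWarning

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.svm import NuSVR
from sklearn.utils.validation import check_is_fitted

from .expression_io import ExpressionMatrix, SignatureMatrix

DEFAULT_NU_GRID = (0.25, 0.50, 0.75)


@dataclass
class CellFractions:
    """Per-sample deconvolved cell-type proportions with fit diagnostics.

    Each row of ``fractions`` is non-negative and sums to one.  ``fit_rmse``
    and ``fit_corr`` measure agreement between the reconstructed and observed
    standardized mixture over the signature genes; ``p_value`` holds optional
    permutation p-values.
    """

    sample_ids: list
    cell_types: list
    fractions: np.ndarray
    fit_rmse: np.ndarray
    fit_corr: np.ndarray
    p_value: np.ndarray | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.fit_rmse = np.asarray(self.fit_rmse, dtype=float)
        self.fit_corr = np.asarray(self.fit_corr, dtype=float)
        n, k = len(self.sample_ids), len(self.cell_types)
        if self.fractions.shape != (n, k):
            raise ValueError("fractions shape does not match labels")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be non-negative")
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each fraction row must sum to 1 within 1e-9")
        if np.any(self.fit_corr < -1 - 1e-12) or np.any(self.fit_corr > 1 + 1e-12):
            raise ValueError("fit_corr must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.cell_types)
        frame["RMSE"] = self.fit_rmse
        frame["Correlation"] = self.fit_corr
        if self.p_value is not None:
            frame["P-value"] = self.p_value
        frame.index.name = "Mixture"
        return frame

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class TCellDensities:
    """Per-sample CD3+ (pan-T) and CD8+ T-cell densities in [0, 1].

    CD3 is the summed fraction of all declared T-cell subsets, CD8 the
    fraction of the declared CD8 subset, so ``0 <= cd8 <= cd3 <= 1`` holds
    for every sample.
    """

    sample_ids: list
    cd3: np.ndarray
    cd8: np.ndarray

    def __post_init__(self):
        self.cd3 = np.asarray(self.cd3, dtype=float)
        self.cd8 = np.asarray(self.cd8, dtype=float)
        n = len(self.sample_ids)
        if self.cd3.shape != (n,) or self.cd8.shape != (n,):
            raise ValueError("cd3/cd8 lengths must match sample_ids")
        eps = 1e-9
        if np.any(self.cd8 < -eps) or np.any(self.cd3 > 1 + eps) or np.any(self.cd8 > self.cd3 + eps):
            raise ValueError("densities must satisfy 0 <= cd8 <= cd3 <= 1")

    def __len__(self):
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cd3": self.cd3, "cd8": self.cd8}, index=self.sample_ids
        ).rename_axis("patient_id")


class DeconvolutionError(ValueError):
    """Raised for degenerate mixtures or insufficient gene overlap."""


class _NuFitFailure(RuntimeError):
    """Internal: one nu value failed numerically; others may still fit."""


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise DeconvolutionError("zero-variance vector: standardization undefined")
    return (v - v.mean()) / sd


def _standardize_signature(sig: np.ndarray) -> np.ndarray:
    # whole-matrix z-score (one mean/sd over all entries): an affine map that
    # preserves convex mixing weights, unlike per-column scaling
    sd = sig.std(ddof=0)
    if sd == 0:
        raise DeconvolutionError("constant signature matrix over shared genes")
    return (sig - sig.mean()) / sd


def _fit_one_nu(signature_std: np.ndarray, mixture_std: np.ndarray, nu: float,
                C: float, max_iter: int = 5000):
    model = NuSVR(kernel="linear", nu=nu, C=C, tol=1e-3, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            model.fit(signature_std, mixture_std)
        except ValueError as exc:  # rare libsvm numerical failure at this nu
            raise _NuFitFailure(str(exc)) from exc
    coefs = model.coef_.ravel()
    recon = model.predict(signature_std)
    resid = recon - mixture_std
    rmse = float(np.sqrt(np.mean(resid**2)))
    corr = float(np.corrcoef(recon, mixture_std)[0, 1]) if recon.std() > 0 else 0.0
    return coefs, rmse, corr


def _select_fit(signature_std: np.ndarray, mixture_std: np.ndarray,
                nu_grid, C: float, max_iter: int = 5000):
    """Fit the nu grid and return the lowest-RMSE fit (no truncation yet)."""
    best = None
    for nu in nu_grid:
        try:
            coefs, rmse, corr = _fit_one_nu(signature_std, mixture_std, nu, C, max_iter)
        except _NuFitFailure:
            continue
        if best is None or rmse < best[1]:
            best = (coefs, rmse, corr)
    if best is None:
        raise DeconvolutionError("support-vector regression failed for every nu")
    return best


def _deconvolve_standardized(signature_std: np.ndarray, mixture_std: np.ndarray,
                             nu_grid, C: float, max_iter: int = 5000):
    """Fit the nu grid, keep the lowest-RMSE fit, truncate and renormalize."""
    coefs, rmse, corr = _select_fit(signature_std, mixture_std, nu_grid, C, max_iter)
    trunc = np.clip(coefs, 0.0, None)
    total = trunc.sum()
    if total <= 0:
        raise DeconvolutionError(
            "all regression coefficients non-positive after truncation "
            "(degenerate mixture)"
        )
    return trunc / total, rmse, corr


def _align(mixture: pd.Series, signature: SignatureMatrix, min_gene_overlap: float):
    shared = [g for g in signature.gene_ids if g in mixture.index]
    if not shared:
        raise DeconvolutionError("empty intersection between mixture and signature genes")
    if len(shared) < min_gene_overlap * len(signature.gene_ids):
        raise DeconvolutionError(
            f"only {len(shared)}/{len(signature.gene_ids)} signature genes present "
            f"in mixture (need >= {min_gene_overlap:.0%})"
        )
    sig_frame = signature.to_frame().loc[shared]
    return mixture.loc[shared].to_numpy(dtype=float), sig_frame.to_numpy(dtype=float)


class SignatureRegressionDeconvolver(BaseEstimator, TransformerMixin):
    """Impute immune-cell fractions from bulk expression by nu-SVR regression.

    scikit-learn-style transformer: ``fit`` records the gene intersection and
    the column-standardized signature, ``transform`` maps a gene-by-sample
    linear-TPM matrix to a :class:`CellFractions` table.

    Parameters
    ----------
    signature : SignatureMatrix
        Reference cell-type profiles (LM22 role).
    nu_grid : iterable of float, default (0.25, 0.5, 0.75)
        Regression-tightness grid; the fit with the lowest reconstruction
        RMSE is selected per sample.
    C : float, default 1.0
        SVR penalty parameter.
    min_gene_overlap : float, default 0.5
        Minimum fraction of signature genes that must be present in the
        mixture's gene set.
    n_permutations : int, default 0
        If positive, attach a per-sample permutation p-value for the fit
        correlation (gene-shuffling null, add-one estimator).
    random_state : int or None
        Seed for the permutation null.
    """

    def __init__(self, signature=None, nu_grid=DEFAULT_NU_GRID, C=1.0,
                 min_gene_overlap=0.5, n_permutations=0, random_state=None):
        self.signature = signature
        self.nu_grid = nu_grid
        self.C = C
        self.min_gene_overlap = min_gene_overlap
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y=None):
        """Record the shared genes between ``X`` and the signature.

        ``X`` may be an :class:`ExpressionMatrix` or a gene-by-sample
        DataFrame on linear scale.
        """
        if self.signature is None:
            raise ValueError("a SignatureMatrix must be supplied")
        frame = self._as_frame(X)
        shared = [g for g in self.signature.gene_ids if g in frame.index]
        if not shared:
            raise DeconvolutionError("empty intersection between mixture and signature genes")
        if len(shared) < self.min_gene_overlap * len(self.signature.gene_ids):
            raise DeconvolutionError(
                f"only {len(shared)}/{len(self.signature.gene_ids)} signature genes "
                f"present (need >= {self.min_gene_overlap:.0%})"
            )
        self.genes_ = shared
        sig = self.signature.to_frame().loc[shared].to_numpy(dtype=float)
        self.signature_std_ = _standardize_signature(sig)
        self.cell_types_ = list(self.signature.cell_types)
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> CellFractions:
        """Deconvolve every sample of ``X`` into cell-type proportions."""
        check_is_fitted(self, "signature_std_")
        frame = self._as_frame(X)
        missing = [g for g in self.genes_ if g not in frame.index]
        if missing:
            raise DeconvolutionError(f"mixture is missing fitted genes, e.g. {missing[:3]}")
        sub = frame.loc[self.genes_]
        k = len(self.cell_types_)
        n = sub.shape[1]
        fractions = np.empty((n, k))
        rmse = np.empty(n)
        corr = np.empty(n)
        pvals = np.empty(n) if self.n_permutations else None
        seeds = _spawn_seeds(self.random_state, n) if self.n_permutations else [None] * n
        for j, sample in enumerate(sub.columns):
            y = sub[sample].to_numpy(dtype=float)
            try:
                y_std = _standardize(y)
                fractions[j], rmse[j], corr[j] = _deconvolve_standardized(
                    self.signature_std_, y_std, self.nu_grid, self.C
                )
                if self.n_permutations:
                    pvals[j] = _permutation_p(
                        self.signature_std_, y, corr[j], self.n_permutations,
                        self.nu_grid, self.C, seeds[j],
                    )
            except DeconvolutionError as exc:
                raise DeconvolutionError(f"sample {sample!r}: {exc}") from exc
        return CellFractions(
            sample_ids=list(sub.columns), cell_types=self.cell_types_,
            fractions=fractions, fit_rmse=rmse, fit_corr=corr, p_value=pvals,
        )

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, ExpressionMatrix):
            if X.scale_tag != "linear":
                raise ValueError("expression must be on linear TPM scale; apply to_linear_tpm")
            return X.to_frame()
        return pd.DataFrame(X)


def _spawn_seeds(random_state, n):
    ss = np.random.SeedSequence(random_state if random_state is not None else 0)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _permutation_p(signature_std, mixture_raw, observed_corr, n_permutations,
                   nu_grid, C, seed) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(mixture_raw)
        try:
            # only the selected-fit correlation enters the null; a shuffle
            # with all-negative coefficients still has a defined correlation
            _, _, corr = _select_fit(signature_std, _standardize(perm), nu_grid, C)
        except DeconvolutionError:
            corr = -np.inf
        if corr >= observed_corr:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def deconvolve_sample(mixture: pd.Series, signature: SignatureMatrix,
                      nu_grid=DEFAULT_NU_GRID, C: float = 1.0,
                      min_gene_overlap: float = 0.5):
    """Deconvolve one mixture vector (indexed by gene symbol).

    Returns ``(fractions, rmse, corr)`` where ``fractions`` is a Series over
    the signature's cell types, non-negative and summing to one.
    """
    mixture = pd.Series(mixture, dtype=float)
    y, sig = _align(mixture, signature, min_gene_overlap)
    sig_std = _standardize_signature(sig)
    fracs, rmse, corr = _deconvolve_standardized(sig_std, _standardize(y), nu_grid, C)
    return pd.Series(fracs, index=signature.cell_types), rmse, corr


def deconvolve_cohort(matrix: ExpressionMatrix, signature: SignatureMatrix,
                      nu_grid=DEFAULT_NU_GRID, n_permutations: int = 0,
                      seed=None, C: float = 1.0,
                      min_gene_overlap: float = 0.5) -> CellFractions:
    """Deconvolve every sample of a cohort; deterministic given ``seed``."""
    dec = SignatureRegressionDeconvolver(
        signature=signature, nu_grid=nu_grid, C=C,
        min_gene_overlap=min_gene_overlap,
        n_permutations=n_permutations, random_state=seed,
    )
    return dec.fit(matrix).transform(matrix)


def permutation_significance(mixture: pd.Series, signature: SignatureMatrix,
                             n_permutations: int = 100, seed=None,
                             nu_grid=DEFAULT_NU_GRID, C: float = 1.0) -> float:
    """Permutation p-value for one mixture's deconvolution fit.

    The null distribution shuffles the mixture values across genes and
    records the selected-fit correlation; the add-one estimator
    ``p = (1 + #{null >= observed}) / (n + 1)`` avoids zero p-values.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    mixture = pd.Series(mixture, dtype=float)
    y, sig = _align(mixture, signature, min_gene_overlap=0.5)
    sig_std = _standardize_signature(sig)
    _, _, corr = _select_fit(sig_std, _standardize(y), nu_grid, C)
    return _permutation_p(sig_std, y, corr, n_permutations, nu_grid, C, seed)


def impute_t_cell_densities(fractions: CellFractions,
                            signature: SignatureMatrix) -> TCellDensities:
    """Derive CD3 (sum of declared T subsets) and CD8 densities from fractions."""
    missing = [t for t in signature.t_cell_types if t not in fractions.cell_types]
    if missing or signature.cd8_type not in fractions.cell_types:
        raise ValueError(f"declared T-cell types missing from fractions: "
                         f"{missing or [signature.cd8_type]}")
    frame = pd.DataFrame(fractions.fractions, columns=fractions.cell_types)
    cd3 = frame[list(signature.t_cell_types)].sum(axis=1).to_numpy()
    cd8 = frame[signature.cd8_type].to_numpy()
    return TCellDensities(sample_ids=list(fractions.sample_ids), cd3=cd3, cd8=cd8)
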