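"""Trait-space PCA: regularized iterative imputation, PCA, karyotype t-tests.

Trait compendia for inbred panels are sparse (each study phenotypes its own
subset of lines), so PCA needs completion first.  ``impute_regularized_pca``
is a regularized iterative PCA: missing cells start at column means, then a
rank-``ncp`` SVD with shrunken singular values rebuilds the matrix and only
the originally missing cells are overwritten, iterating to convergence.
The shrinkage (lambda_k <- (lambda_k^2 - sigma^2) / lambda_k, sigma^2 the
mean discarded squared singular value) keeps the completion from chasing
noise.  PCA of the completed matrix is correlation-based (traits have
heterogeneous units), and inversion effects on projections are tested with
Welch's unequal-variance t between INV and STD homozygotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import KaryotypeTable, TraitMatrix

__all__ = [
    "TraitPcaResult",
    "PcTTest",
    "impute_regularized_pca",
    "pca_traits",
    "pc_karyotype_ttest",
    "select_inversion_trait_set",
]


@dataclass
class TraitPcaResult:
    line_ids: list
    trait_names: list
    scores: np.ndarray  # lines x components
    loadings: np.ndarray  # traits x components, unit-norm columns
    var_explained: np.ndarray
    imputation: dict = field(default_factory=dict)


@dataclass
class PcTTest:
    component: int
    inversion: str
    t: float
    df: float
    p: float
    mean_inv: float
    mean_std: float
    se_inv: float
    se_std: float
    n_inv: int
    n_std: int


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance column during standardization")
    return (X - mu) / sd, mu, sd


def impute_regularized_pca(
    traits: TraitMatrix,
    ncp: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[TraitMatrix, dict]:
    """Complete a trait matrix by regularized iterative PCA.

    Observed cells are never modified.  Returns the completed matrix and
    metadata ``{"ncp", "iterations", "converged"}``.
    """
    X = traits.values.to_numpy(dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if (miss.sum(axis=0) > n - 2).any():
        bad = traits.values.columns[miss.sum(axis=0) > n - 2].tolist()
        raise ValueError(f"traits need >= 2 observed values: {bad}")
    if ncp >= min(n, p):
        raise ValueError(f"ncp={ncp} must be < min(n_lines, n_traits)={min(n, p)}")
    if not miss.any():
        return TraitMatrix(traits.values.copy(), traits.categories), {
            "ncp": ncp, "iterations": 0, "converged": True,
        }

    work = X.copy()
    col_means = np.nanmean(X, axis=0)
    work[miss] = col_means[np.nonzero(miss)[1]]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Z, mu, sd = _standardize(work)
        U, d, Vt = np.linalg.svd(Z, full_matrices=False)
        sigma2 = float(np.mean(d[ncp:] ** 2)) if len(d) > ncp else 0.0
        d_shrunk = np.maximum((d[:ncp] ** 2 - sigma2) / d[:ncp], 0.0)
        recon = (U[:, :ncp] * d_shrunk) @ Vt[:ncp]
        new = recon * sd + mu
        delta = float(np.sqrt(np.mean((new[miss] - work[miss]) ** 2)))
        work[miss] = new[miss]
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"imputation did not converge in {max_iter} iterations (delta={delta:.2e})")
    completed = TraitMatrix(
        pd.DataFrame(work, index=traits.values.index, columns=traits.values.columns),
        traits.categories,
    )
    return completed, {"ncp": ncp, "iterations": it, "converged": converged}


def pca_traits(traits: TraitMatrix, n_components: int = 5) -> TraitPcaResult:
    """Correlation-based PCA of a complete trait matrix."""
    X = traits.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait matrix must be complete (run impute_regularized_pca first)")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = traits.values.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance traits: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    U, d, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, len(d))
    U, d, Vt = U[:, :k], d[:k], Vt[:k]
    for c in range(k):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    total = float(np.sum(Z**2))
    return TraitPcaResult(
        list(traits.values.index),
        list(traits.values.columns),
        U * d,
        Vt.T,
        d**2 / total,
    )


def pc_karyotype_ttest(
    pca: TraitPcaResult,
    karyotypes: KaryotypeTable,
    inversion: str,
    component: int = 0,
) -> PcTTest:
    """Welch two-sample t-test of PC scores, INV vs STD homozygotes.

    Welch (unequal-variance) is the right test here: karyotype classes are
    unbalanced and need not share variance, and the Welch-Satterthwaite df
    is real-valued.
    """
    calls = karyotypes.calls[inversion].reindex(pca.line_ids).to_numpy()
    y = pca.scores[:, component]
    a = y[calls == "INV"]
    b = y[calls == "STD"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 lines per homozygous class (INV={len(a)}, STD={len(b)})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return PcTTest(component, inversion, 0.0, float(len(a) + len(b) - 2), 1.0,
                           float(a.mean()), float(b.mean()), 0.0, 0.0, len(a), len(b))
        raise ValueError("degenerate group variances with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return PcTTest(
        component, inversion, float(res.statistic), float(df), float(res.pvalue),
        float(a.mean()), float(b.mean()), float(np.sqrt(sa)), float(np.sqrt(sb)),
        len(a), len(b),
    )


def select_inversion_trait_set(
    flagged_traits: dict,
    karyotypes: KaryotypeTable,
    inversion: str,
    min_hom_inv_frac: float = 0.05,
) -> list[str]:
    """Traits entering the inversion trait-set PCA.

    ``flagged_traits`` maps trait name -> flagged_associated (bool) for this
    inversion.  The inversion itself must have at least ``min_hom_inv_frac``
    of called lines homozygous INV, else no traits are selected.
    """
    calls = karyotypes.calls[inversion].dropna()
    frac = float((calls == "INV").mean()) if len(calls) else 0.0
    if frac < min_hom_inv_frac:
        return []
    return [t for t, ok in flagged_traits.items() if ok]
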