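"""Mixed-model score-test GWAS under four strategies.

The null model per trait is y = X beta + b + e with b ~ N(0, tau_g K) and
e ~ N(0, tau_e I), X = [intercept, Wolbachia].  REML is exact for a single
random effect: after one eigendecomposition of K the restricted likelihood
is a smooth function of the variance ratio lambda = tau_g / tau_e alone,
profiled over beta and tau_e in closed form and optimized on a 1-D grid
plus Brent refinement.  The boundary tau_g = 0 is permitted.

Each variant is then scored without refitting: T = (g' P y)^2 / (g' P g)
with P the REML projection under the fitted covariance, chi^2_1 under the
null.  The four strategies differ only in the GRM and the trait vector:

* full         — VanRaden full-genome GRM, trait as-is;
* ld           — GCTA GRM on the LD-pruned genome, trait as-is;
* loco         — per arm, the null model refits with the GRM built without
                 that arm, and only that arm's variants are scored;
* factored_out — VanRaden GRM, trait replaced by the residuals of
                 trait ~ inversion karyotypes (categorical).

Permutations shuffle the trait vector across lines (covariates and GRM stay
attached to lines) and refit the null model per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import child_rng
from .data_model import GenotypePanel, KaryotypeTable, LineCovariates, TraitMatrix
from .relatedness import RelatednessMatrix

__all__ = [
    "FACTORED_OUT_INVERSIONS",
    "NullModelFit",
    "GwaRun",
    "fit_null_lmm",
    "score_test",
    "score_test_many",
    "factored_out_residuals",
    "run_gwa",
]

#: inversions regressed out by the Factored-out strategy
FACTORED_OUT_INVERSIONS = ("In(2L)t", "In(2R)NS", "In(3R)P", "In(3R)K", "In(3R)Mo")


@dataclass
class NullModelFit:
    trait: str
    line_ids: list
    lambda_: float  # tau_g / tau_e
    tau_g: float
    tau_e: float
    reml_loglik: float
    # cached projection pieces (rotated basis)
    U: np.ndarray = field(repr=False)  # K eigenvectors
    w: np.ndarray = field(repr=False)  # tau_g * s + tau_e (V eigenvalues)
    UtX: np.ndarray = field(repr=False)
    Uty: np.ndarray = field(repr=False)
    XtVinvX_inv: np.ndarray = field(repr=False)
    XtVinvy: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)

    def project_quadratics(self, G: np.ndarray, rotated: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Return (g' P y, g' P g) for each column of G (already complete).

        ``rotated=True`` means G is already U'G — rotation depends only on
        the GRM, so callers scoring many permutations can cache it.
        """
        Gt = G if rotated else self.U.T @ G  # n x m rotated
        Gw = Gt / self.w[:, None]
        A = self.UtX.T @ Gw  # p x m
        c = self.XtVinvX_inv @ self.XtVinvy
        gPy = Gw.T @ self.Uty - A.T @ c
        gPg = np.einsum("ij,ij->j", Gt, Gw) - np.einsum("ij,ij->j", A, self.XtVinvX_inv @ A)
        return gPy, gPg


@dataclass
class ScoreResult:
    variant_id: str
    n: int
    maf: float
    T: float
    p: float
    beta: float
    se: float


@dataclass
class GwaRun:
    trait: str
    method: str
    results: pd.DataFrame  # id, arm, pos, maf, n, T, p, beta, se
    perm_p: np.ndarray | None = None  # n_perm x n_variants
    seed: int = 0
    trait_sd: float = np.nan
    null_fits: dict = field(default_factory=dict, repr=False)


def _reml_profile(lam: float, s: np.ndarray, UtX: np.ndarray, Uty: np.ndarray):
    """Profiled REML pieces at variance ratio lam; returns (loglik, sigma_e2, beta)."""
    n, p = UtX.shape
    w = lam * s + 1.0
    Xw = UtX / w[:, None]
    XtWX = UtX.T @ Xw
    XtWy = Xw.T @ Uty
    beta = np.linalg.solve(XtWX, XtWy)
    r = Uty - UtX @ beta
    rss = float(np.sum(r * r / w))
    df = n - p
    sigma_e2 = rss / df
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, sigma_e2, beta
    ll = -0.5 * (
        df * np.log(2.0 * np.pi * sigma_e2)
        + np.sum(np.log(w))
        + logdet_xwx
        + df
    )
    return float(ll), sigma_e2, beta


def fit_null_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: RelatednessMatrix,
    trait: str = "trait",
    psd_tol: float = 0.1,
) -> NullModelFit:
    """Exact single-random-effect REML via eigendecomposition of K.

    ``X`` must include the intercept.  The variance ratio is profiled on a
    log-spaced grid over [1e-6, 1e6] (plus 0) and refined with bounded
    Brent minimization; boundary estimates (tau_g = 0) are permitted.

    Pairwise-complete GCTA relatedness can carry slightly negative
    eigenvalues under genotype missingness; eigenvalues above
    ``-psd_tol * trace(K)/n`` are clipped to zero, anything worse raises.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if np.isnan(y).any():
        raise ValueError("y must be complete on included lines")
    if X.shape[0] != n or K.K.shape[0] != n:
        raise ValueError("dimension mismatch between y, X and K")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")
    s, U = K.eig()
    if s[0] < -psd_tol * max(np.trace(K.K) / n, 1.0):
        raise ValueError(f"K is not PSD within tolerance (min eig {s[0]:.3e})")
    s = np.maximum(s, 0.0)
    UtX = U.T @ X
    Uty = U.T @ y

    grid = np.concatenate([[0.0], np.logspace(-6, 6, 49)])
    lls = np.array([_reml_profile(l, s, UtX, Uty)[0] for l in grid])
    i = int(np.nanargmax(lls))
    if i == 0:
        lo, hi = 0.0, grid[1]
    elif i == len(grid) - 1:
        lo, hi = grid[-2], grid[-1]
    else:
        lo, hi = grid[i - 1], grid[i + 1]
    res = optimize.minimize_scalar(
        lambda l: -_reml_profile(l, s, UtX, Uty)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(res.x) if -res.fun >= lls[i] else float(grid[i])
    ll, sigma_e2, beta = _reml_profile(lam, s, UtX, Uty)
    tau_e = sigma_e2
    tau_g = lam * sigma_e2
    w = tau_g * s + tau_e
    Xw = UtX / w[:, None]
    XtVinvX = UtX.T @ Xw
    return NullModelFit(
        trait=trait,
        line_ids=list(K.line_ids),
        lambda_=lam,
        tau_g=tau_g,
        tau_e=tau_e,
        reml_loglik=ll,
        U=U,
        w=w,
        UtX=UtX,
        Uty=Uty,
        XtVinvX_inv=np.linalg.inv(XtVinvX),
        XtVinvy=Xw.T @ Uty,
        beta=beta,
    )


def _prepare_dosages(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages column-wise."""
    G = np.asarray(G, dtype=float).copy()
    nan = np.isnan(G)
    if nan.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(G, axis=0)
        G[nan] = mu[np.nonzero(nan)[1]]
    return G


def score_test_many(fit: NullModelFit, G: np.ndarray, rotated: bool = False, eps: float = 1e-12):
    """Score tests for dosage columns of G; constant columns are skipped (NaN)."""
    if not rotated:
        G = _prepare_dosages(G)
    gPy, gPg = fit.project_quadratics(G, rotated=rotated)
    T = np.full(G.shape[1], np.nan)
    p = np.full(G.shape[1], np.nan)
    ok = gPg > eps
    T[ok] = gPy[ok] ** 2 / gPg[ok]
    p[ok] = stats.chi2.sf(T[ok], df=1)
    beta = np.where(ok, gPy / np.where(ok, gPg, 1.0), np.nan)
    se = np.where(ok, 1.0 / np.sqrt(np.where(ok, gPg, 1.0)), np.nan)
    return T, p, beta, se


def score_test(fit: NullModelFit, g: np.ndarray, variant_id: str = "variant") -> ScoreResult | None:
    """Single-variant score test; returns None for a constant variant."""
    g = np.asarray(g, dtype=float)
    n = int(np.sum(~np.isnan(g)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pfreq = np.nanmean(g) / 2.0
    T, p, beta, se = score_test_many(fit, g[:, None])
    if np.isnan(T[0]):
        return None
    return ScoreResult(variant_id, n, float(min(pfreq, 1 - pfreq)), float(T[0]), float(p[0]), float(beta[0]), float(se[0]))


def factored_out_residuals(
    trait_values: pd.Series,
    karyotypes: KaryotypeTable,
    inversions: tuple = FACTORED_OUT_INVERSIONS,
) -> pd.Series:
    """Residuals of trait ~ inversion karyotypes (each categorical).

    Lines with a missing call for any listed inversion are dropped.
    Collinear dummy columns are handled by least squares (minimum-norm
    solution); absent inversions raise.
    """
    missing = [i for i in inversions if i not in karyotypes.inversions]
    if missing:
        raise ValueError(f"karyotype table lacks inversions: {missing}")
    calls = karyotypes.calls[list(inversions)].reindex(trait_values.index)
    use = trait_values.notna() & calls.notna().all(axis=1)
    y = trait_values[use].to_numpy(dtype=float)
    dummies = pd.get_dummies(calls[use], drop_first=True, dtype=float)
    D = np.column_stack([np.ones(len(y)), dummies.to_numpy()]) if dummies.shape[1] else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return pd.Series(resid, index=trait_values.index[use], name=trait_values.name)


def _gwa_variant_mask(panel: GenotypePanel, line_idx: np.ndarray, maf_min=0.05, missing_max=0.15):
    """Score-stage variant filter on the included lines: maf >= 0.05, missing <= 0.15."""
    D = panel.dosage[line_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pfreq = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(pfreq, 1 - pfreq)
    miss = np.isnan(D).mean(axis=0)
    return np.nan_to_num(maf, nan=0.0) >= maf_min, miss <= missing_max


def run_gwa(
    trait_values: pd.Series,
    panel: GenotypePanel,
    karyotypes: KaryotypeTable,
    covariates: LineCovariates,
    method: str,
    grms: dict,
    n_perm: int = 0,
    seed: int = 0,
    factored_inversions: tuple | None = None,
) -> GwaRun:
    """One trait x one strategy GWAS with optional trait-shuffling permutations.

    ``grms`` maps 'full' -> RelatednessMatrix, 'ld' -> RelatednessMatrix and
    'loco' -> {arm: RelatednessMatrix}.  Returned p-values keep the same
    variant universe across observed and permuted runs.
    """
    if method not in ("full", "ld", "loco", "factored_out"):
        raise ValueError(f"unknown method {method!r}")
    y_series = trait_values.copy()
    if method == "factored_out":
        invs = factored_inversions
        if invs is None:
            invs = tuple(i for i in FACTORED_OUT_INVERSIONS if i in karyotypes.inversions)
            if not invs:
                invs = tuple(karyotypes.inversions)
        y_series = factored_out_residuals(trait_values, karyotypes, invs)

    wolb = covariates.wolbachia_indicator()
    lines = [
        l for l in panel.line_ids
        if l in y_series.index and not np.isnan(y_series[l]) and not np.isnan(wolb.get(l, np.nan))
    ]
    if len(lines) < 3:
        raise ValueError("too few lines with complete trait and covariates")
    line_idx = np.array([panel.line_ids.index(l) for l in lines])
    y = y_series[lines].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(lines)), wolb[lines].to_numpy(dtype=float)])

    maf_ok, miss_ok = _gwa_variant_mask(panel, line_idx)
    vmask = maf_ok & miss_ok
    variants = panel.variants.loc[vmask, ["id", "arm", "pos"]].reset_index(drop=True)
    D = panel.dosage[np.ix_(line_idx, np.flatnonzero(vmask))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pfreq = np.nanmean(D, axis=0) / 2.0
    variants["maf"] = np.minimum(pfreq, 1 - pfreq)
    variants["n"] = (~np.isnan(D)).sum(axis=0)
    G = _prepare_dosages(D)

    def grm_for(key) -> RelatednessMatrix:
        try:
            grm = grms[key] if not isinstance(key, tuple) else grms[key[0]][key[1]]
        except KeyError:
            raise ValueError(f"missing GRM for {key!r}") from None
        if list(grm.line_ids) == lines:
            return grm
        idx = [grm.line_ids.index(l) for l in lines]
        return RelatednessMatrix(lines, grm.K[np.ix_(idx, idx)], grm.method, grm.excluded_arm)

    arm_of = variants["arm"].to_numpy()
    arms = list(pd.unique(arm_of)) if method == "loco" else [None]
    # per-(sub-)GRM cache: rotation of G is permutation-invariant
    blocks = []
    for arm in arms:
        if method == "loco":
            grm = grm_for(("loco", arm))
            cols = np.flatnonzero(arm_of == arm)
        else:
            grm = grm_for("ld" if method == "ld" else "full")
            cols = np.arange(len(variants))
        Gt = grm.eig()[1].T @ G[:, cols]
        blocks.append((arm, grm, cols, Gt))

    def score_vector(yv):
        T = np.full(len(variants), np.nan)
        p = np.full(len(variants), np.nan)
        beta = np.full(len(variants), np.nan)
        se = np.full(len(variants), np.nan)
        fits = {}
        for arm, grm, cols, Gt in blocks:
            fit = fit_null_lmm(yv, X, grm, trait=str(trait_values.name))
            fits[arm] = fit
            T[cols], p[cols], beta[cols], se[cols] = score_test_many(fit, Gt, rotated=True)
        return T, p, beta, se, fits

    T, p, beta, se, fits = score_vector(y)
    results = variants.assign(T=T, p=p, beta=beta, se=se)

    perm_p = None
    if n_perm > 0:
        perm_p = np.empty((n_perm, len(variants)))
        for b in range(n_perm):
            rng = child_rng(seed, "gwa_perm", str(trait_values.name), method, b)
            yb = y[rng.permutation(len(y))]
            perm_p[b] = score_vector(yb)[1]
    return GwaRun(
        trait=str(trait_values.name),
        method=method,
        results=results,
        perm_p=perm_p,
        seed=seed,
        trait_sd=float(np.std(y, ddof=1)),
        null_fits=fits,
    )
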