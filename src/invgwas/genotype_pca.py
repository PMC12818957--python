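"""PCA of genotype panels and quantification of inversion effects on PCs.

Inversions suppress recombination and so dominate genome-wide structure:
on a Full-variant PCA the leading components split lines by karyotype,
while a leave-one-chromosome-out PCA that drops the inversion's arm shows
near-zero karyotype signal.  ``pc_inversion_model`` quantifies this with
an R^2 of PC score on the INV/STD indicator among homozygous lines,
compared against karyotype-shuffling permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import child_rng
from .data_model import GenotypePanel, InversionDef, KaryotypeTable
from .relatedness import RelatednessMatrix

__all__ = [
    "PcaResult",
    "PcInversionModel",
    "pca_genotypes",
    "pc_inversion_model",
    "relatedness_by_karyotype",
    "perm_quantile",
]


def perm_quantile(values: np.ndarray, q: float = 0.95) -> float:
    """Empirical q-quantile as the ceil(q*n)-th order statistic.

    For 100 permutations at q=0.95 this is the 95th smallest value, matching
    the 'surpasses 95% of permutations' rule; 'exceeds' is always strict.
    """
    v = np.sort(np.asarray(values, dtype=float))
    k = int(np.ceil(q * len(v))) - 1
    return float(v[max(k, 0)])


@dataclass
class PcaResult:
    line_ids: list
    scores: np.ndarray  # lines x components
    eigenvalues: np.ndarray  # non-increasing
    var_explained: np.ndarray  # fractions of total standardized variance
    strategy: str = "Full"


@dataclass
class PcInversionModel:
    component: int
    inversion: str
    n: int
    n_inv: int
    n_std: int
    r2: float
    f_stat: float
    df: tuple
    p: float
    perm_r2: np.ndarray = field(repr=False, default=None)
    exceeds_95: bool = False


def pca_genotypes(panel: GenotypePanel, n_components: int = 10, strategy: str = "Full") -> PcaResult:
    """PCA on GCTA-standardized dosages, missing entries zeroed after centering.

    Columns are standardized as (g - 2p) / sqrt(2 p (1 - p)); scores are the
    left singular vectors scaled by singular values.  Sign convention: each
    component's largest-magnitude variant loading is positive.
    """
    if panel.n_lines < 2:
        raise ValueError("need >= 2 lines")
    p = panel.alt_freq()
    poly = (p > 0) & (p < 1)
    if not poly.all():
        panel = panel.subset_variants(poly)
        p = p[poly]
    X = (panel.dosage - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    X = np.where(np.isnan(X), 0.0, X)
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(d > d[0] * 1e-12)) if d.size else 0
    if n_components > rank:
        warnings.warn(f"n_components={n_components} > rank {rank}; truncating")
        n_components = rank
    U, d, Vt = U[:, :n_components], d[:n_components], Vt[:n_components]
    # sign: largest-|loading| positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    m = panel.n_variants
    eigenvalues = d**2 / m  # eigenvalues of the line x line standardized covariance
    total = float(np.sum(X**2)) / m
    return PcaResult(panel.line_ids, U * d, eigenvalues, eigenvalues / total, strategy)


def _two_group_r2(y: np.ndarray, g: np.ndarray) -> tuple[float, float, tuple, float]:
    """R^2, F, dfs, p for OLS of y on a binary indicator g."""
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0
    if ss_tot > 0:
        fit = np.where(g == 1, y[g == 1].mean(), y[g == 0].mean())
        r2 = 1.0 - float(np.sum((y - fit) ** 2)) / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    dfs = (1, n - 2)
    f = np.inf if r2 == 1.0 else (n - 2) * r2 / (1.0 - r2)
    p = float(stats.f.sf(f, *dfs)) if np.isfinite(f) else 0.0
    return r2, f, dfs, p


def pc_inversion_model(
    pca: PcaResult,
    karyotypes: KaryotypeTable,
    inversion: str,
    component: int = 0,
    n_perm: int = 100,
    seed: int = 0,
) -> PcInversionModel:
    """OLS of a PC score on I(INV) among homozygotes, with permutation null.

    Permutations shuffle the karyotype labels among the included homozygous
    lines; ``exceeds_95`` is strict exceedance of the 95th-percentile
    permutation R^2.
    """
    calls = karyotypes.calls[inversion].reindex(pca.line_ids)
    hom = calls.isin(["INV", "STD"]).to_numpy()
    g = (calls.to_numpy() == "INV")[hom].astype(float)
    y = pca.scores[hom, component]
    n_inv, n_std = int(g.sum()), int((1 - g).sum())
    if n_inv < 2 or n_std < 2:
        raise ValueError(f"need >= 2 lines per homozygous class (INV={n_inv}, STD={n_std})")
    r2, f, dfs, p = _two_group_r2(y, g)
    rng = child_rng(seed, "pc_inversion_model", inversion, component)
    perm_r2 = np.empty(n_perm)
    for b in range(n_perm):
        perm_r2[b] = _two_group_r2(y, rng.permutation(g))[0]
    exceeds = bool(n_perm > 0 and r2 > perm_quantile(perm_r2, 0.95))
    return PcInversionModel(
        component, inversion, n_inv + n_std, n_inv, n_std, r2, f, dfs, p, perm_r2, exceeds
    )


def relatedness_by_karyotype(
    K: RelatednessMatrix, karyotypes: KaryotypeTable, inversion: str
) -> dict:
    """Off-diagonal relatedness partitioned into INV/INV, STD/STD, INV/STD pairs.

    Heterozygous and missing-call lines are excluded.  Returns per-class
    means, quantiles and the raw values.
    """
    calls = karyotypes.calls[inversion].reindex(K.line_ids).to_numpy()
    out = {}
    idx = {
        "INV/INV": ("INV", "INV"),
        "STD/STD": ("STD", "STD"),
        "INV/STD": ("INV", "STD"),
    }
    for label, (a, b) in idx.items():
        ia = np.flatnonzero(calls == a)
        ib = np.flatnonzero(calls == b)
        if a == b:
            if len(ia) < 2:
                vals = np.array([])
            else:
                r, c = np.triu_indices(len(ia), k=1)
                vals = K.K[np.ix_(ia, ia)][r, c]
        else:
            vals = K.K[np.ix_(ia, ib)].ravel()
        out[label] = {
            "n_pairs": int(vals.size),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "q25": float(np.quantile(vals, 0.25)) if vals.size else np.nan,
            "q75": float(np.quantile(vals, 0.75)) if vals.size else np.nan,
            "values": vals,
        }
    return out
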