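"""Inversion-trait linear models and the matched-frequency polymorphism null.

Each inversion is tested one at a time against each trait with an OLS model
on karyotype-homozygous lines (heterozygotes carry unknown inversion allele
frequency within a line and are excluded).  Because an inversion is just a
very common polymorphism, its observed R^2 is benchmarked against an
empirical null of random variants matched for allele frequency (+-1%) on
the same arm, at least 2 Mb from the breakpoints and outside the inversion
body.  A trait is flagged inversion-associated when the model is nominally
significant (p < 0.05) AND its R^2 strictly exceeds the 95% quantile of the
matched-variant R^2 distribution.  The ancestry models ask whether admixture
proportion explains the same signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .data_model import GenotypePanel, InversionDef, KaryotypeTable, LineCovariates
from .genotype_pca import perm_quantile

__all__ = [
    "InversionFit",
    "MatchedNullResult",
    "AncestryModelTable",
    "inversion_trait_lm",
    "matched_null",
    "ancestry_models",
    "inversion_allele_frequency",
]


@dataclass
class InversionFit:
    trait: str
    inversion: str
    n: int
    n_inv: int
    n_std: int
    beta: float
    r2: float
    f_stat: float
    p: float


@dataclass
class MatchedNullResult:
    fit: InversionFit
    null_r2: np.ndarray = field(repr=False)
    null_p: np.ndarray = field(repr=False)
    r2_q95: float = np.nan
    significant: bool = False
    exceeds_null: bool = False
    flagged_associated: bool = False
    n_pool: int = 0
    sampled_ids: list = field(default_factory=list, repr=False)


@dataclass
class AncestryModelTable:
    trait: str
    inversion: str
    models: pd.DataFrame  # rows ancestry/inversion/full: r2, f, p, perm_q95, exceeds
    full_vs_ancestry: dict = field(default_factory=dict)
    full_vs_inversion: dict = field(default_factory=dict)
    n: int = 0


def _ols_anova(y: np.ndarray, X: np.ndarray) -> tuple[float, float, tuple, float, np.ndarray]:
    """OLS of y on [1, X]; F test against the intercept-only model."""
    n = len(y)
    D = np.column_stack([np.ones(n), X]) if X.ndim > 0 and X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    rank = np.linalg.matrix_rank(D)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = rank - 1, n - rank
    if tss <= 0 or df1 <= 0 or df2 <= 0:
        return 0.0, 0.0, (max(df1, 0), max(df2, 0)), 1.0, beta
    r2 = min(max(1.0 - rss / tss, 0.0), 1.0)
    if r2 == 1.0:
        return 1.0, np.inf, (df1, df2), 0.0, beta
    f = (r2 / df1) / ((1.0 - r2) / df2)
    return r2, f, (df1, df2), float(stats.f.sf(f, df1, df2)), beta


def inversion_trait_lm(
    trait_values: pd.Series, karyotypes: KaryotypeTable, inversion: str, trait_name: str | None = None
) -> InversionFit:
    """OLS of trait line means on I(INV), homozygous lines only."""
    name = trait_name or (trait_values.name or "trait")
    calls = karyotypes.calls[inversion].reindex(trait_values.index)
    use = calls.isin(["INV", "STD"]) & trait_values.notna()
    y = trait_values[use].to_numpy(dtype=float)
    g = (calls[use] == "INV").to_numpy(dtype=float)
    n_inv, n_std = int(g.sum()), int(len(g) - g.sum())
    if n_inv < 2 or n_std < 2:
        raise ValueError(
            f"{name} x {inversion}: need >= 2 lines per homozygous class (INV={n_inv}, STD={n_std})"
        )
    r2, f, dfs, p, beta = _ols_anova(y, g)
    return InversionFit(name, inversion, len(y), n_inv, n_std, float(beta[1]), r2, f, p)


def inversion_allele_frequency(karyotypes: KaryotypeTable, inversion: str, definition: str = "allele") -> float:
    """Inversion frequency for matching.

    'allele': (2 nINV + nHET) / (2 n_called) — counts heterozygous lines.
    'homozygote': nINV / (nINV + nSTD).
    """
    calls = karyotypes.calls[inversion].dropna()
    n_inv = int((calls == "INV").sum())
    n_het = int((calls == "HET").sum())
    n_std = int((calls == "STD").sum())
    if definition == "allele":
        n_called = n_inv + n_het + n_std
        if n_called == 0:
            raise ValueError(f"no called lines for {inversion}")
        return (2 * n_inv + n_het) / (2 * n_called)
    if definition == "homozygote":
        if n_inv + n_std == 0:
            raise ValueError(f"no homozygous lines for {inversion}")
        return n_inv / (n_inv + n_std)
    raise ValueError(f"unknown frequency definition {definition!r}")


def eligible_matched_pool(
    panel: GenotypePanel,
    inversion: InversionDef,
    target_freq: float,
    freq_tol: float = 0.01,
    min_dist_bp: int = 2_000_000,
) -> np.ndarray:
    """Mask of variants usable as frequency-matched stand-ins for an inversion."""
    v = panel.variants
    folded = min(target_freq, 1.0 - target_freq)
    on_arm = (v["arm"] == inversion.arm).to_numpy()
    freq_ok = (np.abs(panel.maf() - folded) <= freq_tol)
    pos = v["pos"].to_numpy()
    outside = (pos < inversion.start) | (pos > inversion.end)
    far = (np.abs(pos - inversion.start) > min_dist_bp) & (np.abs(pos - inversion.end) > min_dist_bp)
    return on_arm & freq_ok & outside & far


def matched_null(
    trait_values: pd.Series,
    karyotypes: KaryotypeTable,
    inversion: InversionDef,
    panel: GenotypePanel,
    n_draws: int = 100,
    freq_tol: float = 0.01,
    min_dist_bp: int = 2_000_000,
    seed: int = 0,
    freq_definition: str = "allele",
    trait_name: str | None = None,
) -> MatchedNullResult:
    """Benchmark an inversion-trait model against frequency-matched variants.

    For each sampled variant, the same OLS is fit on lines homozygous at
    that variant (dosage 0 or 2) with non-missing trait.  Draws with a
    degenerate genotype class are skipped and redrawn when possible.
    """
    fit = inversion_trait_lm(trait_values, karyotypes, inversion.name, trait_name)
    f = inversion_allele_frequency(karyotypes, inversion.name, freq_definition)
    pool = np.flatnonzero(eligible_matched_pool(panel, inversion, f, freq_tol, min_dist_bp))
    if len(pool) == 0:
        raise ValueError(
            f"empty matched pool for {inversion.name}: arm={inversion.arm}, "
            f"target maf={min(f, 1 - f):.3f}+-{freq_tol}, >{min_dist_bp}bp from breakpoints"
        )
    rng = child_rng(seed, "matched_null", inversion.name, trait_values.name or "trait")
    if len(pool) >= n_draws:
        chosen = rng.choice(pool, size=n_draws, replace=False)
    else:
        warnings.warn(
            f"matched pool ({len(pool)}) smaller than n_draws ({n_draws}); sampling with replacement"
        )
        chosen = rng.choice(pool, size=n_draws, replace=True)

    tv = trait_values.reindex(panel.line_ids)
    y_all = tv.to_numpy(dtype=float)
    null_r2, null_p, used_ids = [], [], []
    for j in chosen:
        g = panel.dosage[:, j]
        use = (~np.isnan(g)) & ((g == 0) | (g == 2)) & ~np.isnan(y_all)
        gi = (g[use] == 2).astype(float)
        if gi.sum() < 2 or (1 - gi).sum() < 2:
            null_r2.append(np.nan)
            null_p.append(np.nan)
            used_ids.append(panel.variants["id"].iloc[j])
            continue
        r2, _, _, p, _ = _ols_anova(y_all[use], gi)
        null_r2.append(r2)
        null_p.append(p)
        used_ids.append(panel.variants["id"].iloc[j])
    null_r2 = np.asarray(null_r2)
    null_p = np.asarray(null_p)
    ok = ~np.isnan(null_r2)
    if ok.sum() < n_draws:
        warnings.warn(f"{int(n_draws - ok.sum())} matched draws degenerate; using {int(ok.sum())}")
    r2_q95 = perm_quantile(null_r2[ok], 0.95) if ok.any() else np.nan
    significant = fit.p < 0.05
    exceeds = bool(ok.any() and fit.r2 > r2_q95)
    return MatchedNullResult(
        fit, null_r2, null_p, r2_q95, significant, exceeds,
        significant and exceeds, len(pool), used_ids,
    )


def ancestry_models(
    trait_values: pd.Series,
    karyotypes: KaryotypeTable,
    covariates: LineCovariates,
    inversion: str,
    n_perm: int = 100,
    seed: int = 0,
) -> AncestryModelTable:
    """Ancestry-only, Inversion-only and Full models vs null, with permutations.

    All three models are F-tested against the intercept-only null; the Full
    model is additionally tested against each single-predictor model with a
    nested F test.  Permutations shuffle the trait vector across the
    included lines and are compared at the 95% quantile of permuted R^2
    (nested tests: permuted F).
    """
    anc = covariates.ancestry_african
    if anc is None:
        raise ValueError("ancestry covariate required")
    calls = karyotypes.calls[inversion].reindex(trait_values.index)
    anc = anc.reindex(trait_values.index)
    use = calls.isin(["INV", "STD"]) & trait_values.notna() & anc.notna()
    n_dropped = int((~use).sum())
    if n_dropped:
        warnings.warn(f"{inversion}: dropped {n_dropped} lines (het/missing trait/ancestry)")
    y = trait_values[use].to_numpy(dtype=float)
    g = (calls[use] == "INV").to_numpy(dtype=float)
    a = anc[use].to_numpy(dtype=float)
    designs = {
        "ancestry": a[:, None],
        "inversion": g[:, None],
        "full": np.column_stack([a, g]),
    }

    def fit_all(yv):
        rows = {}
        for mname, X in designs.items():
            r2, f, dfs, p, _ = _ols_anova(yv, X)
            rows[mname] = {"r2": r2, "f": f, "p": p}
        # nested comparisons
        nested = {}
        for mname in ("ancestry", "inversion"):
            r2_r = rows[mname]["r2"]
            r2_f = rows["full"]["r2"]
            df2 = len(yv) - 3
            num = max(r2_f - r2_r, 0.0)
            fstat = np.inf if r2_f >= 1.0 else (num / 1.0) / ((1.0 - r2_f) / df2)
            pval = float(stats.f.sf(fstat, 1, df2)) if np.isfinite(fstat) else 0.0
            nested[f"full_vs_{mname}"] = {"f": fstat, "p": pval, "delta_r2": num}
        return rows, nested

    obs_rows, obs_nested = fit_all(y)
    rng = child_rng(seed, "ancestry_models", inversion, trait_values.name or "trait")
    perm_r2 = {m: np.empty(n_perm) for m in designs}
    perm_f = {k: np.empty(n_perm) for k in obs_nested}
    for b in range(n_perm):
        rows, nested = fit_all(rng.permutation(y))
        for m in designs:
            perm_r2[m][b] = rows[m]["r2"]
        for k in nested:
            perm_f[k][b] = nested[k]["f"]

    table = []
    for m in designs:
        q95 = perm_quantile(perm_r2[m], 0.95) if n_perm else np.nan
        table.append(
            {
                "model": m, **obs_rows[m],
                "perm_q95": q95,
                "exceeds": bool(n_perm and obs_rows[m]["r2"] > q95),
            }
        )
    for k in obs_nested:
        q95 = perm_quantile(perm_f[k][np.isfinite(perm_f[k])], 0.95) if n_perm else np.nan
        obs_nested[k]["perm_q95"] = q95
        obs_nested[k]["exceeds"] = bool(n_perm and obs_nested[k]["f"] > q95)
    return AncestryModelTable(
        trait_values.name or "trait", inversion, pd.DataFrame(table).set_index("model"),
        obs_nested["full_vs_ancestry"], obs_nested["full_vs_inversion"], int(use.sum()),
    )
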