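"""Bin-level GWAS summaries: hit proportions, genomic inflation, exceedance.

Variants are binned by (arm, inside/outside inversion); breakpoint-buffer
variants count as outside.  Per bin: the proportion of variants with
p < 1e-5 ("hits") and the genomic inflation factor, the median of the
chi^2_1 quantile transform of the bin's p-values divided by the chi^2_1
median (~0.4549).  Observed bin statistics are compared with the trait's
permutation distribution at the strict 95th-order-statistic rule, and
exceedance proportions between methods or regions are contrasted with
Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import InversionDef
from .genotype_pca import perm_quantile
from .lmm_gwa import GwaRun

__all__ = [
    "CHI2_1_MEDIAN",
    "BinSummary",
    "summarize_bins",
    "summarize_pvalues",
    "exceedance",
    "compare_exceedance_fet",
    "wilson_ci",
]

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class BinSummary:
    trait: str
    method: str
    arm: str
    region: str  # inside | outside
    n: int
    hit_proportion: float
    gif: float


def _region_labels(variants: pd.DataFrame, inversions) -> np.ndarray:
    """inside/outside labels; breakpoint buffers binarize to outside."""
    lab = np.full(len(variants), "outside", dtype=object)
    pos = variants["pos"].to_numpy()
    arm = variants["arm"].to_numpy()
    for inv in inversions:
        inside = (arm == inv.arm) & (pos >= inv.start) & (pos <= inv.end)
        lab[inside] = "inside"
    return lab


def summarize_pvalues(p: np.ndarray, p_threshold: float = 1e-5) -> tuple[int, float, float]:
    """(n, hit proportion, GIF) for one bin's p-values (NaNs excluded)."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    n = len(p)
    if n == 0:
        return 0, np.nan, np.nan
    hits = float(np.mean(p < p_threshold))
    chi2 = stats.chi2.isf(p, df=1)
    gif = float(np.median(chi2) / CHI2_1_MEDIAN)
    return n, hits, gif


def summarize_bins(
    run: GwaRun,
    inversions,
    p_threshold: float = 1e-5,
    p_matrix_row: np.ndarray | None = None,
) -> list[BinSummary]:
    """Per-(arm, region) summaries for an observed run or one permutation row."""
    labels = _region_labels(run.results, inversions)
    p = run.results["p"].to_numpy() if p_matrix_row is None else p_matrix_row
    out = []
    for arm in pd.unique(run.results["arm"]):
        for region in ("inside", "outside"):
            sel = (run.results["arm"].to_numpy() == arm) & (labels == region)
            n, hits, gif = summarize_pvalues(p[sel], p_threshold)
            out.append(BinSummary(run.trait, run.method, arm, region, n, hits, gif))
    return out


def exceedance(
    observed: list[BinSummary],
    permuted: list[list[BinSummary]],
    q: float = 0.95,
) -> pd.DataFrame:
    """Strict exceedance of observed bin statistics over permutation quantiles.

    ``permuted`` is one BinSummary list per permutation, over the same bins.
    Returns rows keyed by (trait, method, arm, region, statistic).
    """
    if len(permuted) < 20:
        warnings.warn(f"only {len(permuted)} permutations; exceedance quantiles are coarse")
    key = lambda b: (b.trait, b.method, b.arm, b.region)
    obs_by_key = {key(b): b for b in observed}
    perm_by_key: dict = {k: {"hits": [], "gif": []} for k in obs_by_key}
    for rep in permuted:
        seen = set()
        for b in rep:
            k = key(b)
            if k not in perm_by_key:
                raise ValueError(f"permuted bin {k} not present in observed bins")
            perm_by_key[k]["hits"].append(b.hit_proportion)
            perm_by_key[k]["gif"].append(b.gif)
            seen.add(k)
        if seen != set(obs_by_key):
            raise ValueError("mismatched bins between observed and a permutation")
    rows = []
    for k, b in obs_by_key.items():
        for stat, obs_val in (("hits", b.hit_proportion), ("gif", b.gif)):
            vals = np.asarray(perm_by_key[k][stat], dtype=float)
            vals = vals[~np.isnan(vals)]
            q95 = perm_quantile(vals, q) if len(vals) else np.nan
            rows.append(
                {
                    "trait": b.trait, "method": b.method, "arm": b.arm, "region": b.region,
                    "statistic": stat, "observed": obs_val, "perm_q95": q95,
                    "n_perm": len(vals),
                    "exceeds": bool(len(vals) and not np.isnan(obs_val) and obs_val > q95),
                }
            )
    return pd.DataFrame(rows)


def compare_exceedance_fet(flags_a, flags_b) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test on exceedance proportions of two trait groups.

    ``flags_a``/``flags_b`` are boolean vectors (one entry per trait) of
    'exceeds permutations'.  Returns (sample odds ratio, two-sided p, 2x2
    table).  With a zero margin the raw OR is inf/0/nan; a Haldane-corrected
    (+0.5) auxiliary OR is returned in its place alongside the exact p.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    table = np.array(
        [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]], dtype=float
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
        or_ = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    else:
        or_ = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(or_), float(p), table.astype(int)


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)
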