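"""Enrichment of top GWAS hits in external candidate-outlier sets.

Candidate sets (e.g. population-differentiation XtX* or environmental
Bayes-factor outliers with POD-calibrated empirical p-values) are consumed
as inputs.  The top-k hits of a GWAS run are intersected with the outlier
flags over the run's own variant universe in a 2x2 Fisher's exact test, and
the observed odds ratio is compared with odds ratios computed identically
from the run's trait permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_pca import perm_quantile
from .gwa_summary import wilson_ci
from .lmm_gwa import GwaRun
from .synthetic_data import CandidateSet

__all__ = ["top_hits", "top_hits_from_pvalues", "enrichment_fet", "enrichment_exceedance"]


def top_hits_from_pvalues(results: pd.DataFrame, p: np.ndarray, k: int = 500) -> set:
    """ids of the k smallest p-values; ties broken by (arm, pos)."""
    df = results[["id", "arm", "pos"]].assign(p=p).dropna(subset=["p"])
    if len(df) < k:
        warnings.warn(f"only {len(df)} scored variants < k={k}; returning all")
        k = len(df)
    df = df.sort_values(["p", "arm", "pos"], kind="mergesort")
    return set(df["id"].iloc[:k])


def top_hits(run: GwaRun, k: int = 500) -> set:
    """The k lowest-p variants of a run, deterministically tie-broken."""
    if len(run.results) == 0:
        raise ValueError("empty run")
    return top_hits_from_pvalues(run.results, run.results["p"].to_numpy(), k)


def enrichment_fet(top: set, candidates: CandidateSet, universe) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test of (in top) x (outlier) over the variant universe.

    Returns (odds ratio, two-sided p, 2x2 table); with a zero cell the OR is
    Haldane-corrected (+0.5).
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    if not set(top) <= uset:
        raise ValueError("top hits must be a subset of the universe")
    outliers = candidates.outlier_ids & uset
    a = len(set(top) & outliers)
    b = len(set(top) - outliers)
    c = len(outliers - set(top))
    d = len(uset) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table + 0.5 if (table == 0).any() else table
    or_ = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(or_), float(p), table.astype(int)


def enrichment_exceedance(observed_or: float, permuted_ors, q: float = 0.95) -> bool:
    """Does the observed enrichment OR strictly exceed the permutation q-quantile?"""
    vals = np.asarray(list(permuted_ors), dtype=float)
    n_bad = int(np.sum(~np.isfinite(vals)))
    if n_bad:
        warnings.warn(f"excluding {n_bad} undefined permuted ORs")
        vals = vals[np.isfinite(vals)]
    if len(vals) < 20:
        warnings.warn(f"only {len(vals)} usable permuted ORs; quantile is coarse")
    if len(vals) == 0 or not np.isfinite(observed_or):
        return False
    return bool(observed_or > perm_quantile(vals, q))


def exceedance_proportion(flags) -> dict:
    """Proportion of traits whose enrichment exceeds permutations, with Wilson CI."""
    flags = np.asarray(list(flags), dtype=bool)
    k, n = int(flags.sum()), len(flags)
    lo, hi = wilson_ci(k, n) if n else (np.nan, np.nan)
    return {"k": k, "n": n, "proportion": k / n if n else np.nan, "ci_low": lo, "ci_high": hi}
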