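"""Genomic relatedness matrices: VanRaden (Full), GCTA (LD-pruned), LOCO.

Three GRM families control population structure in the mixed-model GWAS:

* ``vanraden_full`` — VanRaden's K = Z Z' / (2 * sum_j p_j (1 - p_j)) on all
  variants passing maf > 0.05 and missing < 0.20, with missing dosages
  mean-imputed before centering.
* ``gcta_ld`` — the GCTA estimator, per-variant standardized products
  averaged with pairwise-complete counts, on an LD-pruned set
  (maf > 0.05, missing < 0.15, pairwise r^2 < 0.2 within 5 kb).
* ``gcta_loco`` — the GCTA recipe on all arms except one, so variants on the
  excluded arm (and any inversion there) do not contribute to relatedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import GenotypePanel, filter_variants

__all__ = ["RelatednessMatrix", "grm_vanraden", "ld_prune", "grm_gcta", "grm_loco", "build_grm"]


@dataclass
class RelatednessMatrix:
    line_ids: list
    K: np.ndarray
    method: str  # vanraden_full | gcta_ld | gcta_loco
    excluded_arm: str | None = None
    variant_set_descriptor: str = ""

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if K.shape != (len(self.line_ids), len(self.line_ids)):
            raise ValueError("K dimensions must match line_ids")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        self.K = (K + K.T) / 2.0
        self._eig = None

    def eig(self):
        """Cached eigendecomposition (ascending eigenvalues), for REML reuse."""
        if self._eig is None:
            w, U = np.linalg.eigh(self.K)
            self._eig = (w, U)
        return self._eig

    def min_eigenvalue(self) -> float:
        return float(self.eig()[0][0])


def _drop_degenerate(panel: GenotypePanel, require_polymorphic: bool, context: str) -> GenotypePanel:
    miss = panel.missing_rate()
    if (miss == 1.0).any():
        bad = panel.variants.loc[miss == 1.0, "id"].tolist()
        raise ValueError(f"{context}: all-missing variants (pre-filter them): {bad[:5]}")
    p = panel.alt_freq()
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        if require_polymorphic:
            bad = panel.variants.loc[mono, "id"].tolist()
            raise ValueError(f"{context}: monomorphic variants: {bad[:5]}")
        warnings.warn(f"{context}: dropping {int(mono.sum())} monomorphic variants")
        panel = panel.subset_variants(~mono)
    return panel


def grm_vanraden(panel: GenotypePanel) -> RelatednessMatrix:
    """VanRaden GRM: K = Z Z' / (2 * sum p(1-p)), missing mean-imputed to 2p."""
    if panel.n_lines < 2 or panel.n_variants < 1:
        raise ValueError("need >= 2 lines and >= 1 variant")
    panel = _drop_degenerate(panel, require_polymorphic=False, context="grm_vanraden")
    p = panel.alt_freq()
    D = panel.dosage.copy()
    nan = np.isnan(D)
    D[nan] = (2.0 * p)[np.nonzero(nan)[1]]
    Z = D - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    K = Z @ Z.T / denom
    return RelatednessMatrix(
        panel.line_ids, K, "vanraden_full",
        variant_set_descriptor=f"n_variants={panel.n_variants}",
    )


def ld_prune(panel: GenotypePanel, r2_max: float = 0.2, window_bp: int = 5000) -> list[str]:
    """Greedy left-to-right LD pruning within each arm.

    Scanning variants in position order, a candidate is dropped if its
    squared Pearson correlation of dosages with any already-retained variant
    at pairwise distance <= ``window_bp`` exceeds ``r2_max``.  Earlier
    position wins ties; correlations use pairwise-complete lines.
    """
    kept: list[str] = []
    for arm in panel.variants["arm"].unique():
        sub = panel.variants[panel.variants["arm"] == arm].sort_values("pos")
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        retained: list[int] = []  # positions into idx
        for i in range(len(idx)):
            gi = panel.dosage[:, idx[i]]
            ok = True
            for r in reversed(retained):
                if pos[i] - pos[r] > window_bp:
                    break
                gr = panel.dosage[:, idx[r]]
                both = ~np.isnan(gi) & ~np.isnan(gr)
                if both.sum() < 2:
                    continue
                a, b = gi[both], gr[both]
                sa, sb = a.std(), b.std()
                if sa == 0 or sb == 0:
                    continue
                r2 = (np.corrcoef(a, b)[0, 1]) ** 2
                if r2 > r2_max:
                    ok = False
                    break
            if ok:
                retained.append(i)
        kept.extend(sub["id"].iloc[retained].tolist())
    order = {v: i for i, v in enumerate(panel.variants["id"])}
    return sorted(kept, key=order.__getitem__)


def grm_gcta(panel: GenotypePanel, method_tag: str = "gcta_ld", excluded_arm: str | None = None) -> RelatednessMatrix:
    """GCTA GRM: averaged per-variant standardized products.

    K_jk = (1 / M_jk) * sum_i (g_ji - 2 p_i)(g_ki - 2 p_i) / (2 p_i (1 - p_i)),
    with missing entries excluded pairwise (per-pair variant count M_jk).
    """
    if panel.n_lines < 2 or panel.n_variants < 1:
        raise ValueError("need >= 2 lines and >= 1 variant")
    panel = _drop_degenerate(panel, require_polymorphic=True, context="grm_gcta")
    p = panel.alt_freq()
    X = (panel.dosage - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    M = obs.astype(float) @ obs.astype(float).T
    if (M == 0).any():
        raise ValueError("some line pairs share no observed variants")
    K = (X0 @ X0.T) / M
    return RelatednessMatrix(
        panel.line_ids, K, method_tag, excluded_arm=excluded_arm,
        variant_set_descriptor=f"n_variants={panel.n_variants}",
    )


def grm_loco(panel: GenotypePanel, excluded_arm: str) -> RelatednessMatrix:
    """GCTA GRM on the variant subset with arm != ``excluded_arm``."""
    keep = (panel.variants["arm"] != excluded_arm).to_numpy()
    if not keep.any():
        raise ValueError(f"no variants remain after excluding arm {excluded_arm!r}")
    return grm_gcta(panel.subset_variants(keep), method_tag="gcta_loco", excluded_arm=excluded_arm)


def build_grm(
    panel: GenotypePanel,
    method: str,
    excluded_arm: str | None = None,
    r2_max: float = 0.2,
    window_bp: int = 5000,
) -> RelatednessMatrix:
    """Apply a full GRM recipe (variant filters + pruning + estimator).

    method 'full': maf > 0.05, missing < 0.20, VanRaden.
    method 'ld':   maf > 0.05, missing < 0.15, LD-pruned, GCTA.
    method 'loco': the LD recipe restricted to arms != excluded_arm.
    """
    if method == "full":
        return grm_vanraden(filter_variants(panel, 0.05, 0.20))
    if method not in ("ld", "loco"):
        raise ValueError(f"unknown GRM method {method!r}")
    sub = filter_variants(panel, 0.05, 0.15)
    if method == "loco":
        if excluded_arm is None:
            raise ValueError("loco requires excluded_arm")
        keep = (sub.variants["arm"] != excluded_arm).to_numpy()
        if not keep.any():
            raise ValueError(f"no variants remain after excluding arm {excluded_arm!r}")
        sub = sub.subset_variants(keep)
    pruned = sub.subset_variants(ld_prune(sub, r2_max, window_bp))
    tag = "gcta_ld" if method == "ld" else "gcta_loco"
    return grm_gcta(pruned, method_tag=tag, excluded_arm=excluded_arm)
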