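"""Synthetic DGRP-like panels: inbred lines, inversions, LD, and traits.

The generator emulates the statistical structure the downstream analyses
assume, not fly population history.  Each line draws an inversion karyotype
(INV with probability ``q``, optionally HET); variants inside an inversion
or within its leakage zone tag the karyotype through a haplotype model in
which a line's allele matches its arrangement's haplotype allele with
probability ``1 - leak(d)``, where ``leak(d) = min(leak0 + d / leak_length,
0.5)`` and ``d`` is the distance to the nearest breakpoint (0 inside).
Variants beyond the leakage zone draw an allele frequency from a Beta MAF
spectrum.  Traits are line means built from an inversion effect calibrated
to a target variance fraction, a polygenic background, a Wolbachia effect,
and residual noise.

All draws come from Philox counter-based streams keyed by component name
(see :mod:`invgwas._rng`), so a fixed master seed is bit-reproducible and
adding traits never perturbs genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .data_model import (
    DEFAULT_GENOME,
    TRAIT_CATEGORIES,
    GenotypePanel,
    InversionDef,
    KaryotypeTable,
    LineCovariates,
    TraitMatrix,
)

__all__ = [
    "InversionSimSpec",
    "SimConfig",
    "TraitSimConfig",
    "CandidateSet",
    "simulate_panel",
    "simulate_traits",
    "simulate_candidate_sets",
    "leak_probability",
    "folded_beta_mean",
]


@dataclass(frozen=True)
class InversionSimSpec:
    """One simulated inversion: breakpoints, line frequency, HET fraction."""

    name: str = "In(2L)t"
    arm: str = "2L"
    start: int = 2_225_744  # In(2L)t-like proximal breakpoint
    end: int = 13_154_180  # In(2L)t-like distal breakpoint
    freq: float = 0.25  # probability a line is INV-homozygous
    het_fraction: float = 0.0  # panel is inbred; >0 only to exercise exclusions

    def __post_init__(self):
        if not (0.0 <= self.freq <= 1.0 and 0.0 <= self.het_fraction <= 1.0):
            raise ValueError("freq and het_fraction must be in [0, 1]")

    def to_def(self, buffer_bp: int = 2_000_000) -> InversionDef:
        return InversionDef(self.name, self.arm, self.start, self.end, buffer_bp)


@dataclass
class SimConfig:
    """Scenario for :func:`simulate_panel` (DGRP-like defaults)."""

    n_lines: int = 200
    genome: dict = field(default_factory=lambda: dict(DEFAULT_GENOME))
    inversions: tuple = (InversionSimSpec(),)
    n_variants_per_arm: int | dict = 500  # int, or {arm: count}
    maf_beta: tuple = (0.5, 2.5)  # Beta(a, b) allele-frequency spectrum
    missing_rate: float = 0.03  # MCAR genotype missingness
    leak0: float = 0.02  # tagging error at the breakpoints / inside
    leak_length: float = 4_000_000.0  # bp scale of LD decay beyond breakpoints
    ancestry_beta: tuple = (1.5, 6.0)  # African-ancestry proportion spectrum
    ancestry_inv_shift: float = 0.0  # optional karyotype-ancestry correlation
    wolbachia_freq: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if any(l <= 0 for l in self.genome.values()):
            raise ValueError("arm lengths must be positive")


@dataclass
class TraitSimConfig:
    """Scenario for :func:`simulate_traits`.

    Variance fractions are of a unit-variance trait: ``r2_inv`` for the
    inversion (the ~10% scale seen for inversion-associated line means),
    ``polygenic_var`` spread over ``n_polygenic`` background loci,
    ``wolbachia_var`` for infection status, remainder residual.
    ``inv_loading`` gives each trait's sign on the shared inversion axis
    (0 drops the effect for that trait); default alternating +/- signs.
    """

    n_traits: int = 20
    r2_inv: float = 0.10
    inv_loading: tuple | None = None
    n_polygenic: int = 50
    polygenic_var: float = 0.25
    wolbachia_var: float = 0.02
    trait_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.r2_inv < 1.0):
            raise ValueError("r2_inv must be in [0, 1)")
        rest = self.r2_inv + self.polygenic_var + self.wolbachia_var
        if rest >= 1.0:
            raise ValueError("variance fractions exceed 1")
        if self.inv_loading is not None and len(self.inv_loading) != self.n_traits:
            raise ValueError("inv_loading length must equal n_traits")

    @property
    def residual_var(self) -> float:
        return 1.0 - self.r2_inv - self.polygenic_var - self.wolbachia_var


def leak_probability(dist_bp: np.ndarray, leak0: float, leak_length: float) -> np.ndarray:
    """Haplotype-tagging error rate at distance ``dist_bp`` from a breakpoint."""
    return np.minimum(leak0 + np.asarray(dist_bp, dtype=float) / leak_length, 0.5)


def folded_beta_mean(a: float, b: float, n_grid: int = 200_001) -> float:
    """Mean of min(p, 1-p) for p ~ Beta(a, b), by numerical integration."""
    from scipy import integrate, stats

    x = np.linspace(0.0, 1.0, n_grid)[1:-1]
    y = np.minimum(x, 1 - x) * stats.beta.pdf(x, a, b)
    return float(integrate.trapezoid(y, x))


def simulate_panel(cfg: SimConfig):
    """Draw a panel: (GenotypePanel, KaryotypeTable, [InversionDef], LineCovariates)."""
    line_ids = [f"line_{i:03d}" for i in range(cfg.n_lines)]

    # karyotypes: HET with prob het_fraction, else INV w.p. freq, else STD
    kary = {}
    for inv in cfg.inversions:
        if inv.freq * cfg.n_lines < 2:
            warnings.warn(
                f"{inv.name}: expected INV lines < 2; inversion-conditioned analyses will be degenerate"
            )
        rng = child_rng(cfg.seed, "karyotype", inv.name)
        u_het = rng.random(cfg.n_lines)
        u_inv = rng.random(cfg.n_lines)
        calls = np.where(u_het < inv.het_fraction, "HET", np.where(u_inv < inv.freq, "INV", "STD"))
        kary[inv.name] = calls
    karyotypes = KaryotypeTable(pd.DataFrame(kary, index=line_ids))

    inv_by_arm: dict[str, list[InversionSimSpec]] = {}
    for inv in cfg.inversions:
        inv_by_arm.setdefault(inv.arm, []).append(inv)

    meta, cols = [], []
    for arm_i, (arm, length) in enumerate(sorted(cfg.genome.items())):
        rng = child_rng(cfg.seed, "genotypes", arm)
        n_var = (
            cfg.n_variants_per_arm[arm]
            if isinstance(cfg.n_variants_per_arm, dict)
            else cfg.n_variants_per_arm
        )
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_var, replace=False))
        for j, p_bp in enumerate(pos):
            vid = f"{arm}:{p_bp}"
            tag_inv = None
            dist = None
            for inv in inv_by_arm.get(arm, []):
                d = 0 if inv.start <= p_bp <= inv.end else min(abs(p_bp - inv.start), abs(p_bp - inv.end))
                lk = leak_probability(d, cfg.leak0, cfg.leak_length)
                if lk < 0.5 and (dist is None or d < dist):
                    tag_inv, dist = inv, d
            if tag_inv is not None:
                lk = float(leak_probability(dist, cfg.leak0, cfg.leak_length))
                calls = karyotypes.calls[tag_inv.name].to_numpy()
                # INV haplotype carries the alt allele, STD the ref
                hap1 = np.where(calls == "STD", 0, 1)
                hap2 = np.where(calls == "INV", 1, 0)
                flip1 = rng.random(cfg.n_lines) < lk
                flip2 = rng.random(cfg.n_lines) < lk
                a1 = np.where(flip1, 1 - hap1, hap1)
                a2 = np.where(flip2, 1 - hap2, hap2)
                inside = dist == 0
                if inside:
                    dos = (a1 + a2).astype(float)
                else:
                    # outside the body recombination in HET ancestors homogenizes;
                    # treat the line as inbred for one drawn haplotype
                    dos = 2.0 * a1
            else:
                p = rng.beta(*cfg.maf_beta)
                dos = 2.0 * (rng.random(cfg.n_lines) < p)
            meta.append({"id": vid, "arm": arm, "pos": int(p_bp), "ref": "A", "alt": "T"})
            cols.append(dos)

    dosage = np.array(cols, dtype=float).T
    miss_rng = child_rng(cfg.seed, "missingness")
    if cfg.missing_rate > 0:
        mask = miss_rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    panel = GenotypePanel(line_ids, pd.DataFrame(meta), dosage)

    cov_rng = child_rng(cfg.seed, "covariates")
    wolb = np.where(cov_rng.random(cfg.n_lines) < cfg.wolbachia_freq, "present", "absent")
    anc = cov_rng.beta(*cfg.ancestry_beta, size=cfg.n_lines)
    if cfg.ancestry_inv_shift and cfg.inversions:
        first = cfg.inversions[0].name
        is_inv = (karyotypes.calls[first] == "INV").to_numpy()
        anc = np.clip(anc + cfg.ancestry_inv_shift * is_inv, 0.0, 1.0)
    covariates = LineCovariates(
        pd.DataFrame({"wolbachia": wolb, "ancestry_african": anc}, index=line_ids)
    )

    inv_defs = [inv.to_def() for inv in cfg.inversions]
    return panel, karyotypes, inv_defs, covariates


def simulate_traits(
    panel: GenotypePanel,
    karyotypes: KaryotypeTable,
    covariates: LineCovariates,
    cfg: TraitSimConfig,
    inversion: str | None = None,
    inversion_defs: list[InversionDef] | None = None,
) -> TraitMatrix:
    """Simulate trait line means with a calibrated inversion variance share.

    y = beta_inv * I(INV) + sum_j beta_j g_j + beta_w * wolbachia + eps.
    ``beta_inv`` is solved from the empirical variance of the karyotype
    indicator so the expected share of trait variance equals ``r2_inv``;
    polygenic and Wolbachia effects are scaled the same way.
    """
    if list(panel.line_ids) != list(karyotypes.line_ids):
        raise ValueError("panel and karyotypes must share line_ids")
    inversion = inversion or karyotypes.inversions[0]
    n = panel.n_lines
    ind = (karyotypes.calls[inversion] == "INV").to_numpy(dtype=float)
    var_ind = ind.var()
    if cfg.r2_inv > 0 and var_ind == 0:
        raise ValueError(
            f"r2_inv={cfg.r2_inv} unattainable: karyotype indicator for {inversion} has zero variance"
        )

    loadings = cfg.inv_loading
    if loadings is None:
        loadings = tuple(1.0 if t % 2 == 0 else -1.0 for t in range(cfg.n_traits))

    wolb = covariates.wolbachia_indicator().to_numpy(dtype=float)
    wolb = np.nan_to_num(wolb, nan=0.0)
    var_wolb = wolb.var()

    sel_rng = child_rng(cfg.seed, "traits", "loci")
    # polygenic loci: polymorphic and off inversion arms so the background is
    # independent of karyotype tagging; missing dosages mean-imputed
    cand = panel.maf() > 0.05
    if inversion_defs:
        inv_arms = {d.arm for d in inversion_defs}
        cand &= ~panel.variants["arm"].isin(inv_arms).to_numpy()
    values = {}
    for t in range(cfg.n_traits):
        rng = child_rng(cfg.seed, "traits", t)
        y = np.zeros(n)
        if cfg.r2_inv > 0 and loadings[t] != 0:
            beta_inv = np.sign(loadings[t]) * np.sqrt(cfg.r2_inv / var_ind)
            y += beta_inv * ind
        if cfg.polygenic_var > 0 and cfg.n_polygenic > 0:
            if t == 0 and cand.sum() < cfg.n_polygenic:
                warnings.warn(
                    f"only {int(cand.sum())} eligible polygenic loci (requested {cfg.n_polygenic}); "
                    "the polygenic background will be coarse"
                    + (" or absent" if cand.sum() == 0 else "")
                )
            idx = sel_rng.choice(np.flatnonzero(cand), size=min(cfg.n_polygenic, int(cand.sum())), replace=False)
            G = panel.dosage[:, idx].copy()
            nanmask = np.isnan(G)
            if nanmask.any():
                mu = np.nanmean(G, axis=0)
                G[nanmask] = mu[np.nonzero(nanmask)[1]]
            betas = rng.standard_normal(len(idx))
            score = G @ betas
            sv = score.var()
            if sv > 0:
                y += score * np.sqrt(cfg.polygenic_var / sv)
        if cfg.wolbachia_var > 0 and var_wolb > 0:
            y += wolb * np.sqrt(cfg.wolbachia_var / var_wolb)
        y += rng.standard_normal(n) * np.sqrt(cfg.residual_var)
        if cfg.trait_missing_rate > 0:
            y = y.copy()
            y[rng.random(n) < cfg.trait_missing_rate] = np.nan
        values[f"trait_{t:03d}"] = y

    cats = pd.Series(
        [TRAIT_CATEGORIES[t % 5] for t in range(cfg.n_traits)],
        index=list(values.keys()),
    )
    return TraitMatrix(pd.DataFrame(values, index=panel.line_ids), cats)


@dataclass
class CandidateSet:
    """External candidate-outlier calls (XtX*/BF-style) with empirical p-values."""

    table: pd.DataFrame  # columns: id, statistic, value, empirical_p, outlier

    def __post_init__(self):
        want = (self.table["empirical_p"] < 0.05).to_numpy()
        if not (self.table["outlier"].to_numpy(dtype=bool) == want).all():
            raise ValueError("outlier flags inconsistent with empirical p < 0.05")

    @property
    def outlier_ids(self) -> set:
        return set(self.table.loc[self.table["outlier"], "id"])


def simulate_candidate_sets(
    panel: GenotypePanel,
    enriched_region: InversionDef | None,
    frac_outliers: float = 0.05,
    enrichment_factor: float = 1.0,
    seed: int = 0,
    statistic: str = "XtX*",
) -> CandidateSet:
    """Flag variants as outliers with a base rate, enriched inside a region.

    Empirical p-values are drawn consistently with the flag: U(0, 0.05) for
    outliers, U(0.05, 1) otherwise.
    """
    if not (0.0 <= frac_outliers < 1.0):
        raise ValueError("frac_outliers must be in [0, 1)")
    rng = child_rng(seed, "candidates", statistic)
    rate = np.full(panel.n_variants, frac_outliers)
    if enriched_region is not None:
        inside = (
            (panel.variants["arm"] == enriched_region.arm)
            & (panel.variants["pos"] >= enriched_region.start)
            & (panel.variants["pos"] <= enriched_region.end)
        ).to_numpy()
        rate[inside] = np.minimum(frac_outliers * enrichment_factor, 0.999)
    outlier = rng.random(panel.n_variants) < rate
    emp_p = np.where(
        outlier,
        rng.uniform(0.0, 0.05, panel.n_variants),
        rng.uniform(0.05, 1.0, panel.n_variants),
    )
    value = -np.log10(np.maximum(emp_p, 1e-12))  # monotone stand-in statistic
    return CandidateSet(
        pd.DataFrame(
            {
                "id": panel.variants["id"].to_numpy(),
                "statistic": statistic,
                "value": value,
                "empirical_p": emp_p,
                "outlier": outlier,
            }
        )
    )
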