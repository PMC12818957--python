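"""End-to-end scenario runs: simulate -> GRMs -> PCAs -> association -> GWA
-> summaries -> enrichment -> colocalization, with provenance.

A scenario is a :class:`RunConfig` (loadable from YAML).  ``run_scenario``
executes every stage into an output directory as TSV/JSON artifacts and
writes a provenance file (config hash, master seed, package version) first,
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import sliding_coloc
from .data_model import (
    filter_traits,
    filter_variants,
    write_covariates,
    write_genotypes,
    write_inversions,
    write_karyotypes,
    write_traits,
)
from .enrichment import enrichment_exceedance, enrichment_fet, top_hits, top_hits_from_pvalues
from .genotype_pca import pc_inversion_model, pca_genotypes, relatedness_by_karyotype
from .gwa_summary import exceedance, summarize_bins
from .inversion_association import matched_null
from .lmm_gwa import run_gwa
from .relatedness import build_grm
from .synthetic_data import (
    InversionSimSpec,
    SimConfig,
    TraitSimConfig,
    simulate_candidate_sets,
    simulate_panel,
    simulate_traits,
)
from .trait_pca import impute_regularized_pca, pc_karyotype_ttest, pca_traits

log = logging.getLogger("invgwas")

__all__ = ["RunConfig", "run_scenario", "demo_config"]


@dataclass
class RunConfig:
    """Desk-scale scenario configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    traits: TraitSimConfig = field(default_factory=TraitSimConfig)
    methods: tuple = ("full", "ld", "loco", "factored_out")
    n_perm: int = 25
    p_threshold: float = 1e-5
    top_k: int = 500
    min_lines_per_trait: int = 75
    coloc_window_bp: int = 10_000
    coloc_step_bp: int = 5_000
    matched_null_draws: int = 100
    matched_null_min_dist_bp: int = 2_000_000
    seed: int = 0
    out_dir: str = "results/scenario"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        invs = tuple(InversionSimSpec(**i) for i in sim_raw.pop("inversions", [])) or (InversionSimSpec(),)
        sim = SimConfig(inversions=invs, **sim_raw)
        traits = TraitSimConfig(**raw.pop("traits", {}))
        return cls(sim=sim, traits=traits, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["inversions"] = [asdict(i) for i in self.sim.inversions]
        # JSON round-trip normalizes tuples to lists so YAML round-trips compare equal
        return json.loads(json.dumps(d))


def demo_config(seed: int = 0, out_dir: str = "results/demo") -> RunConfig:
    """The packaged demo scenario: 200 lines, one inversion at q = 0.25,
    20 traits at a 10% inversion variance share, 25 permutations."""
    return RunConfig(seed=seed, out_dir=out_dir)


def _sync_seeds(cfg: RunConfig) -> RunConfig:
    cfg.sim.seed = cfg.seed
    cfg.traits.seed = cfg.seed
    return cfg


def run_scenario(cfg: RunConfig) -> Path:
    """Run every stage of the scenario; returns the artifact directory."""
    cfg = _sync_seeds(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": cfg.seed,
        "invgwas_version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "config.yaml").write_text(cfg_yaml)

    timers = {}

    def stage(name):
        log.info("stage %s", name)
        timers[name] = time.perf_counter()

    def done(name):
        timers[name] = round(time.perf_counter() - timers[name], 3)

    # 1. simulate
    stage("simulate")
    panel, karyotypes, inv_defs, covariates = simulate_panel(cfg.sim)
    traits = simulate_traits(panel, karyotypes, covariates, cfg.traits, inversion_defs=inv_defs)
    traits = filter_traits(traits, min(cfg.min_lines_per_trait, panel.n_lines))
    write_genotypes(panel, out / "genotypes.vcf", dialect="vcf")
    write_karyotypes(karyotypes, out / "karyotypes.tsv")
    write_inversions(inv_defs, out / "inversions.tsv")
    write_covariates(covariates, out / "covariates.tsv")
    write_traits(traits, out / "traits.tsv", out / "trait_categories.tsv")
    done("simulate")

    inv = inv_defs[0]

    # 2. GRMs
    stage("grm")
    arms = sorted(cfg.sim.genome)
    grms = {
        "full": build_grm(panel, "full"),
        "ld": build_grm(panel, "ld"),
        "loco": {arm: build_grm(panel, "loco", excluded_arm=arm) for arm in arms},
    }
    for key, grm in [("full", grms["full"]), ("ld", grms["ld"])] + [
        (f"loco_{a}", g) for a, g in grms["loco"].items()
    ]:
        pd.DataFrame(grm.K, index=grm.line_ids, columns=grm.line_ids).to_csv(
            out / f"grm_{key}.tsv", sep="\t"
        )
    rel = {
        m: {k: v["mean"] for k, v in relatedness_by_karyotype(g, karyotypes, inv.name).items()}
        for m, g in [("full", grms["full"]), ("ld", grms["ld"]), ("loco_excl", grms["loco"][inv.arm])]
    }
    pd.DataFrame(rel).to_csv(out / "relatedness_by_karyotype.tsv", sep="\t")
    done("grm")

    # 3. genotype PCA x strategy, PC ~ inversion models
    stage("genotype_pca")
    strat_panels = {
        "Full": filter_variants(panel, 0.05, 0.20),
        "LD": None,  # built from the ld GRM recipe below
    }
    from .relatedness import ld_prune

    ld_panel = filter_variants(panel, 0.05, 0.15)
    strat_panels["LD"] = ld_panel.subset_variants(ld_prune(ld_panel))
    loco_sub = ld_panel.subset_variants((ld_panel.variants["arm"] != inv.arm).to_numpy())
    strat_panels[f"LOCO({inv.arm})"] = loco_sub.subset_variants(ld_prune(loco_sub))
    pc_rows = []
    for strat, sp in strat_panels.items():
        pca = pca_genotypes(sp, n_components=4, strategy=strat)
        pd.DataFrame(pca.scores, index=pca.line_ids).to_csv(out / f"geno_pca_{strat}.tsv", sep="\t")
        for comp in range(2):
            m = pc_inversion_model(pca, karyotypes, inv.name, comp, n_perm=cfg.n_perm, seed=cfg.seed)
            pc_rows.append(
                {"strategy": strat, "component": comp + 1, "r2": m.r2, "p": m.p, "exceeds_95": m.exceeds_95}
            )
    pd.DataFrame(pc_rows).to_csv(out / "geno_pc_inversion_models.tsv", sep="\t", index=False)
    done("genotype_pca")

    # 4. inversion-trait association with matched null
    stage("inversion_association")
    assoc_rows = []
    flags = {}
    for t in traits.trait_names:
        r = matched_null(
            traits.values[t], karyotypes, inv, panel,
            n_draws=cfg.matched_null_draws, min_dist_bp=cfg.matched_null_min_dist_bp,
            seed=cfg.seed,
        )
        flags[t] = r.flagged_associated
        assoc_rows.append(
            {
                "trait": t, "inversion": inv.name, "n": r.fit.n, "beta": r.fit.beta,
                "r2": r.fit.r2, "p": r.fit.p, "null_r2_q95": r.r2_q95,
                "significant": r.significant, "exceeds_null": r.exceeds_null,
                "flagged_associated": r.flagged_associated,
            }
        )
    pd.DataFrame(assoc_rows).to_csv(out / "inversion_association.tsv", sep="\t", index=False)
    done("inversion_association")

    # 5. trait PCA on the inversion-associated set (fallback: all traits)
    stage("trait_pca")
    assoc_traits = [t for t, ok in flags.items() if ok] or traits.trait_names
    sub = filter_traits(
        type(traits)(traits.values[assoc_traits], traits.categories[assoc_traits]), 2
    )
    completed, meta = impute_regularized_pca(sub, ncp=min(2, len(assoc_traits) - 1))
    tp = pca_traits(completed, n_components=min(5, len(assoc_traits)))
    pd.DataFrame(tp.scores, index=tp.line_ids).to_csv(out / "trait_pca_scores.tsv", sep="\t")
    pd.DataFrame(tp.loadings, index=tp.trait_names).to_csv(out / "trait_pca_loadings.tsv", sep="\t")
    tt_rows = []
    for comp in range(min(2, tp.scores.shape[1])):
        tt = pc_karyotype_ttest(tp, karyotypes, inv.name, comp)
        tt_rows.append({"component": comp + 1, "t": tt.t, "df": tt.df, "p": tt.p})
    pd.DataFrame(tt_rows).to_csv(out / "trait_pc_ttests.tsv", sep="\t", index=False)
    done("trait_pca")

    # 6. GWA x methods on the two trait-PC projections + first trait
    stage("gwa")
    pc_traits_df = pd.DataFrame(
        tp.scores[:, : min(2, tp.scores.shape[1])],
        index=tp.line_ids,
        columns=[f"PC{i+1}" for i in range(min(2, tp.scores.shape[1]))],
    )
    gwa_targets = {c: pc_traits_df[c] for c in pc_traits_df.columns}
    gwa_targets[traits.trait_names[0]] = traits.values[traits.trait_names[0]]
    runs = {}
    obs_bins, perm_bins = [], {}
    for method in cfg.methods:
        for tname, tv in gwa_targets.items():
            run = run_gwa(tv, panel, karyotypes, covariates, method, grms, n_perm=cfg.n_perm, seed=cfg.seed)
            runs[(method, tname)] = run
            run.results.to_csv(out / f"gwa_{method}_{tname}.tsv", sep="\t", index=False)
            obs_bins.extend(summarize_bins(run, inv_defs, cfg.p_threshold))
            if run.perm_p is not None:
                perm_bins[(method, tname)] = [
                    summarize_bins(run, inv_defs, cfg.p_threshold, p_matrix_row=row)
                    for row in run.perm_p
                ]
    done("gwa")

    # 7. summaries + exceedance
    stage("summary")
    pd.DataFrame([vars(b) for b in obs_bins]).to_csv(out / "bin_summaries.tsv", sep="\t", index=False)
    exc_frames = []
    for (method, tname), reps in perm_bins.items():
        obs = [b for b in obs_bins if b.method == method and b.trait == tname]
        exc_frames.append(exceedance(obs, reps))
    if exc_frames:
        pd.concat(exc_frames).to_csv(out / "exceedance.tsv", sep="\t", index=False)
    done("summary")

    # 8. enrichment against simulated candidate sets
    stage("enrichment")
    cand = simulate_candidate_sets(panel, inv, frac_outliers=0.05, enrichment_factor=5.0, seed=cfg.seed)
    cand.table.to_csv(out / "candidates.tsv", sep="\t", index=False)
    enr_rows = []
    for (method, tname), run in runs.items():
        universe = run.results["id"].tolist()
        k = min(cfg.top_k, len(universe))
        or_obs, p_obs, _ = enrichment_fet(top_hits(run, k), cand, universe)
        perm_ors = []
        if run.perm_p is not None:
            for row in run.perm_p:
                t = top_hits_from_pvalues(run.results, row, k)
                perm_ors.append(enrichment_fet(t, cand, universe)[0])
        enr_rows.append(
            {
                "method": method, "trait": tname, "odds_ratio": or_obs, "p": p_obs,
                "exceeds_perm": enrichment_exceedance(or_obs, perm_ors) if perm_ors else None,
            }
        )
    pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    done("enrichment")

    # 9. colocalization of PC1 x PC2 under LOCO and Factored-out
    stage("coloc")
    if "PC2" in pc_traits_df.columns:
        for method in [m for m in ("loco", "factored_out") if m in cfg.methods]:
            wins = sliding_coloc(
                runs[(method, "PC1")], runs[(method, "PC2")],
                cfg.coloc_window_bp, cfg.coloc_step_bp,
            )
            pd.DataFrame(
                [
                    {
                        "arm": w.arm, "start": w.start, "end": w.end, "n_snps": w.n_snps,
                        **{h: (w.pp[i] if w.pp is not None else np.nan) for i, h in enumerate(
                            ("PP0", "PP1", "PP2", "PP3", "PP4"))},
                        "top": w.top_hypothesis, "skipped": w.skipped,
                    }
                    for w in wins
                ]
            ).to_csv(out / f"coloc_{method}.tsv", sep="\t", index=False)
    done("coloc")

    (out / "timings.json").write_text(json.dumps(timers, indent=2))
    return out
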