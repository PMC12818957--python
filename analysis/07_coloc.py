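#!/usr/bin/env python
"""Colocalization of PC1 and PC2 association signal over sliding windows.

Dense-region scenario: a 2 Mb arm carrying the inversion at 3.3 kb median
variant spacing, plus a sparser background arm.  Both trait projections load
on the inversion (opposite signs), so the karyotype acts as a shared causal
locus.  Windows of 10 kb (step 5 kb) are classified by the dominant
colocalization hypothesis under LOCO and Factored-out statistics.
"""

import warnings
from collections import Counter
from pathlib import Path

import pandas as pd

from invgwas.coloc import sliding_coloc
from invgwas.lmm_gwa import run_gwa
from invgwas.relatedness import build_grm
from invgwas.synthetic_data import (
    InversionSimSpec, SimConfig, TraitSimConfig, simulate_panel, simulate_traits,
)

OUT = Path("results/analysis")
SEED = 1


def main():
    sim = SimConfig(
        n_lines=200,
        genome={"2L": 2_000_000, "3R": 10_000_000},
        inversions=(InversionSimSpec("In(2L)t", "2L", 500_000, 1_300_000, freq=0.3),),
        n_variants_per_arm={"2L": 600, "3R": 200},
        leak_length=150_000.0,
        missing_rate=0.0,
        seed=SEED,
    )
    panel, kary, invs, cov = simulate_panel(sim)
    traits = simulate_traits(
        panel, kary, cov,
        TraitSimConfig(n_traits=2, r2_inv=0.2, inv_loading=(1.0, -1.0), seed=SEED),
        inversion_defs=invs,
    )
    grms = {
        "full": build_grm(panel, "full"),
        "loco": {a: build_grm(panel, "loco", excluded_arm=a) for a in ("2L", "3R")},
    }
    inv = invs[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("loco", "factored_out"):
            runs = [
                run_gwa(traits.values[t], panel, kary, cov, method, grms, n_perm=0,
                        seed=SEED, factored_inversions=(inv.name,))
                for t in traits.trait_names
            ]
            wins = sliding_coloc(runs[0], runs[1], min_snps=5)
            rows = [
                {"arm": w.arm, "start": w.start, "end": w.end, "n_snps": w.n_snps,
                 **({f"PP{i}": w.pp[i] for i in range(5)} if w.pp is not None else {}),
                 "top": w.top_hypothesis, "skipped": w.skipped}
                for w in wins
            ]
            pd.DataFrame(rows).to_csv(OUT / f"coloc_{method}.tsv", sep="\t", index=False)
            scored = [w for w in wins if not w.skipped and w.arm == "2L"]
            body = [w for w in scored if w.start < inv.end and w.end > inv.start]
            counts = Counter(w.top_hypothesis for w in body)
            print(f"{method}: {len(scored)} scored 2L windows; inversion-body window "
                  f"classes: {dict(counts)}")
    print("-> shared (PP4) colocalization blankets the inversion body only under "
          "LOCO statistics; residualizing the karyotype (Factored-out) erases it")


if __name__ == "__main__":
    main()
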