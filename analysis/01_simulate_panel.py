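#!/usr/bin/env python
"""Simulate the DGRP-like study panel and write its data files.

200 fully inbred lines; one In(2L)t-like inversion segregating at line
frequency 0.25 whose karyotype is tagged by variants inside and near the
inverted region; 5 chromosome arms x 500 biallelic variants with a Beta MAF
spectrum and 3% missingness; Wolbachia status and African-ancestry fractions;
20 trait line means, half loading positively and half negatively on the
inversion with a 10% inversion variance share and 20% missing entries (each
study in a trait compendium phenotypes its own subset of lines).
"""

from pathlib import Path

from invgwas.data_model import (
    write_covariates, write_genotypes, write_inversions, write_karyotypes, write_traits,
)
from invgwas.synthetic_data import SimConfig, TraitSimConfig, simulate_panel, simulate_traits

OUT = Path("results/analysis/data")
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    panel, kary, invs, cov = simulate_panel(SimConfig(seed=SEED))
    traits = simulate_traits(
        panel, kary, cov, TraitSimConfig(trait_missing_rate=0.2, seed=SEED), inversion_defs=invs
    )
    write_genotypes(panel, OUT / "genotypes.vcf")
    write_karyotypes(kary, OUT / "karyotypes.tsv")
    write_inversions(invs, OUT / "inversions.tsv")
    write_covariates(cov, OUT / "covariates.tsv")
    write_traits(traits, OUT / "traits.tsv", OUT / "trait_categories.tsv")

    inv = invs[0]
    n_inv = int((kary.calls[inv.name] == "INV").sum())
    print(f"panel: {panel.n_lines} lines x {panel.n_variants} variants -> {OUT}")
    print(f"{inv.name} [{inv.arm}:{inv.start:,}-{inv.end:,}]: {n_inv} INV-homozygous lines "
          f"({n_inv / panel.n_lines:.0%})")
    print(f"traits: {len(traits.trait_names)} line means, target inversion share 10%")


if __name__ == "__main__":
    main()
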