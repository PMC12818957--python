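#!/usr/bin/env python
"""PCA of the inversion-associated trait set after regularized imputation.

Missing trait means are completed by regularized iterative PCA, the
completed matrix gets a correlation-based PCA, and the INV and STD
homozygote groups are compared on each leading component with Welch's
t-test.  Writes scores, loadings and the t-test table.
"""

import warnings
from pathlib import Path

import pandas as pd

from invgwas.data_model import TraitMatrix, read_karyotypes, read_traits
from invgwas.trait_pca import impute_regularized_pca, pc_karyotype_ttest, pca_traits

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def main():
    kary = read_karyotypes(DATA / "karyotypes.tsv")
    traits = read_traits(DATA / "traits.tsv", DATA / "trait_categories.tsv")
    assoc = pd.read_csv(OUT / "inversion_association.tsv", sep="\t")
    flagged = assoc.loc[assoc.flagged_associated, "trait"].tolist() or traits.trait_names
    sub = TraitMatrix(traits.values[flagged], traits.categories[flagged])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed, meta = impute_regularized_pca(sub, ncp=2)
        res = pca_traits(completed, n_components=min(5, len(flagged)))
    pd.DataFrame(res.scores, index=res.line_ids).to_csv(OUT / "trait_pca_scores.tsv", sep="\t")
    pd.DataFrame(res.loadings, index=res.trait_names).to_csv(OUT / "trait_pca_loadings.tsv", sep="\t")

    inv = kary.inversions[0]
    rows = []
    for comp in range(min(2, res.scores.shape[1])):
        tt = pc_karyotype_ttest(res, kary, inv, comp)
        rows.append({"component": comp + 1, "t": tt.t, "df": tt.df, "p": tt.p,
                     "mean_inv": tt.mean_inv, "mean_std": tt.mean_std})
    tdf = pd.DataFrame(rows)
    tdf.to_csv(OUT / "trait_pc_ttests.tsv", sep="\t", index=False)

    print(f"trait set: {len(flagged)} inversion-associated traits "
          f"(imputation converged: {meta['converged']}, {meta['iterations']} iterations)")
    print(f"PC1/PC2 explain {res.var_explained[:2].sum():.0%} of trait variance")
    for r in rows:
        verdict = "separates" if r["p"] < 0.05 else "does not separate"
        print(f"PC{r['component']} {verdict} karyotypes: t = {r['t']:.2f}, "
              f"df = {r['df']:.1f}, p = {r['p']:.2e}")


if __name__ == "__main__":
    main()
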