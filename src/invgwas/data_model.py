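"""Domain containers and I/O for inbred-line genotype / karyotype / trait data.

The panel model mirrors the DGRP: ~200 fully inbred lines, biallelic SNPs
and small indels coded as alternate-allele dosages in {0, 1, 2} with NaN for
missing calls, per-line inversion karyotypes in {INV, STD, HET}, and traits
measured as per-line means.  Genotypes are read from GT-only biallelic VCF
(via cyvcf2) or from TSV matrices; all other tables are TSV.

Coordinates are 1-based inclusive for variants and inversion breakpoints
(VCF convention).  Filtering thresholds are strict inequalities: a variant
is kept when ``maf > maf_min`` and ``missing_rate < missing_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KARYOTYPE_STATES",
    "VariantRecord",
    "GenotypePanel",
    "KaryotypeTable",
    "InversionDef",
    "TraitMatrix",
    "LineCovariates",
    "read_genotypes",
    "write_genotypes",
    "filter_variants",
    "filter_traits",
    "classify_region",
    "read_karyotypes",
    "write_karyotypes",
    "read_traits",
    "write_traits",
    "read_inversions",
    "write_inversions",
    "read_covariates",
    "write_covariates",
]

KARYOTYPE_STATES = ("INV", "STD", "HET")

#: default chromosome-arm lengths (bp), D. melanogaster major arms
DEFAULT_GENOME = {
    "2L": 23_500_000,
    "2R": 25_000_000,
    "3L": 28_000_000,
    "3R": 32_000_000,
    "X": 23_500_000,
}

TRAIT_CATEGORIES = (
    "Behavior",
    "Life-History",
    "Morphology",
    "Physiology",
    "Stress-resistance",
    "other",
)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant: identity, location, and panel-level stats."""

    id: str
    arm: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float = np.nan
    missing_rate: float = np.nan

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class InversionDef:
    """A polymorphic inversion: arm and 1-based inclusive breakpoints."""

    name: str
    arm: str
    start: int
    end: int
    buffer_bp: int = 2_000_000

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"inversion {self.name}: start must be < end")


class GenotypePanel:
    """Line x variant alternate-allele dosage matrix with variant metadata.

    ``dosage`` is float with entries in {0, 1, 2} and NaN for missing;
    fully inbred panels carry only {0, 2, NaN}.  ``variants`` is a DataFrame
    with columns id, arm, pos, ref, alt, maf, missing_rate; ``maf`` and
    ``missing_rate`` are always derived from the current dosage matrix.
    """

    def __init__(self, line_ids: Sequence[str], variants: pd.DataFrame, dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(line_ids), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} != (n_lines={len(line_ids)}, n_variants={len(variants)})"
            )
        if variants["id"].duplicated().any():
            dups = variants.loc[variants["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")
        self.line_ids = list(line_ids)
        self.variants = variants.reset_index(drop=True).copy()
        self.dosage = dosage
        self._refresh_stats()

    # -- derived stats -------------------------------------------------
    def _refresh_stats(self) -> None:
        self.variants["maf"] = self.maf()
        self.variants["missing_rate"] = self.missing_rate()

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant, from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_records(self) -> list[VariantRecord]:
        return [VariantRecord(**row) for row in self.variants.to_dict("records")]

    # -- subsetting ----------------------------------------------------
    def subset_variants(self, mask_or_ids) -> "GenotypePanel":
        if isinstance(mask_or_ids, (list, set, frozenset, pd.Index)):
            mask = self.variants["id"].isin(set(mask_or_ids)).to_numpy()
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        return GenotypePanel(
            self.line_ids,
            self.variants.loc[mask, ["id", "arm", "pos", "ref", "alt"]],
            self.dosage[:, mask],
        )

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.line_ids.index(l) for l in line_ids]
        return GenotypePanel(
            [self.line_ids[i] for i in idx],
            self.variants[["id", "arm", "pos", "ref", "alt"]],
            self.dosage[idx, :],
        )


@dataclass
class KaryotypeTable:
    """Line x inversion calls over {INV, STD, HET} with NaN/None for missing."""

    calls: pd.DataFrame  # index: line ids; columns: inversion names

    def __post_init__(self):
        vals = self.calls.to_numpy(dtype=object)
        bad = {
            v for v in vals.ravel() if not (v is None or (isinstance(v, float) and np.isnan(v)) or v in KARYOTYPE_STATES)
        }
        if bad:
            raise ValueError(f"invalid karyotype calls: {sorted(map(str, bad))}")
        if self.calls.columns.duplicated().any():
            raise ValueError("inversion names must be unique")

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def inversions(self) -> list[str]:
        return list(self.calls.columns)

    def call(self, inversion: str) -> pd.Series:
        return self.calls[inversion]

    def homozygote_mask(self, inversion: str) -> pd.Series:
        c = self.calls[inversion]
        return c.isin(["INV", "STD"])


@dataclass
class TraitMatrix:
    """Line x trait means with per-trait category labels."""

    values: pd.DataFrame  # index: line ids; columns: trait names
    categories: pd.Series = None  # trait -> category

    def __post_init__(self):
        if self.categories is None:
            self.categories = pd.Series("other", index=self.values.columns)
        self.categories = self.categories.reindex(self.values.columns).fillna("other")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def n_lines_per_trait(self) -> pd.Series:
        return self.values.notna().sum(axis=0)


@dataclass
class LineCovariates:
    """Per-line covariates: Wolbachia infection status and optional ancestry."""

    table: pd.DataFrame  # index: line ids; columns: wolbachia, [ancestry_african]

    def __post_init__(self):
        if "wolbachia" not in self.table.columns:
            raise ValueError("covariates require a 'wolbachia' column")
        bad = set(self.table["wolbachia"].dropna()) - {"present", "absent"}
        if bad:
            raise ValueError(f"wolbachia must be present/absent, got {sorted(bad)}")
        if "ancestry_african" in self.table.columns:
            a = self.table["ancestry_african"].dropna()
            if ((a < 0) | (a > 1)).any():
                raise ValueError("ancestry fractions must be in [0, 1]")

    @property
    def line_ids(self) -> list[str]:
        return list(self.table.index)

    def wolbachia_indicator(self) -> pd.Series:
        """1.0 for present, 0.0 for absent, NaN for missing."""
        return self.table["wolbachia"].map({"present": 1.0, "absent": 0.0})

    @property
    def ancestry_african(self) -> pd.Series | None:
        if "ancestry_african" in self.table.columns:
            return self.table["ancestry_african"]
        return None


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def _tsv_variant_meta(vid: str) -> tuple[str, int, str, str]:
    """Variant metadata encoded in a TSV column id as 'arm:pos:ref:alt'."""
    parts = vid.split(":")
    if len(parts) != 4:
        raise ValueError(
            f"TSV variant id {vid!r} must be 'arm:pos:ref:alt' so metadata is recoverable"
        )
    arm, pos, ref, alt = parts
    return arm, int(pos), ref, alt


def read_genotypes(path: str | Path, dialect: str = "vcf") -> GenotypePanel:
    """Read a biallelic genotype panel from a VCF or a TSV dosage matrix.

    VCF: GT-only, biallelic; dosage is the alt-allele count per line.
    Multi-allelic records are rejected and reported in a warning.
    TSV: tab-separated, header row of 'arm:pos:ref:alt' ids, line ids in the
    first column, cells in {0,1,2} or NA.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    meta, rows = [], []
    skipped = []
    seen = set()
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            skipped.append(v.ID or f"{v.CHROM}:{v.POS}")
            continue
        vid = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        if vid in seen:
            raise ValueError(f"duplicate variant id {vid!r} at record {i + 1}")
        seen.add(vid)
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = v.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        meta.append({"id": vid, "arm": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]})
        rows.append(dos)
    if skipped:
        warnings.warn(f"rejected {len(skipped)} multi-allelic records: {skipped[:5]}...")
    if not meta:
        raise ValueError(f"no biallelic records in {path}")
    dosage = np.vstack(rows).T  # lines x variants
    return GenotypePanel(line_ids, pd.DataFrame(meta), dosage)


def _read_genotype_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = []
    for vid in df.columns:
        arm, pos, ref, alt = _tsv_variant_meta(vid)
        meta.append({"id": vid, "arm": arm, "pos": pos, "ref": ref, "alt": alt})
    return GenotypePanel(list(df.index.astype(str)), pd.DataFrame(meta), df.to_numpy(dtype=float))


def write_genotypes(panel: GenotypePanel, path: str | Path, dialect: str = "vcf") -> None:
    path = Path(path)
    if dialect == "tsv":
        ids = [
            f"{r.arm}:{r.pos}:{r.ref}:{r.alt}" for r in panel.variants.itertuples()
        ]
        df = pd.DataFrame(panel.dosage, index=panel.line_ids, columns=ids)
        # integer-looking cells keep round-trips exact
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f", index_label="line_id")
        return
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    order = np.lexsort((panel.variants["pos"].to_numpy(), panel.variants["arm"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for arm in pd.unique(panel.variants["arm"].to_numpy()[order]):
            length = DEFAULT_GENOME.get(arm, int(panel.variants.loc[panel.variants.arm == arm, "pos"].max()) + 1)
            fh.write(f"##contig=<ID={arm},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.line_ids) + "\n")
        for j in order:
            r = panel.variants.iloc[j]
            calls = [gt_of.get(d, "./.") for d in panel.dosage[:, j]]
            fh.write(f"{r.arm}\t{r.pos}\t{r.id}\t{r.ref}\t{r.alt}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# filtering and region classification
# ---------------------------------------------------------------------------

def filter_variants(panel: GenotypePanel, maf_min: float = 0.05, missing_max: float = 0.20) -> GenotypePanel:
    """Keep variants with ``maf > maf_min`` and ``missing_rate < missing_max``.

    Both inequalities are strict, so boundary values are excluded.  Order is
    preserved; an empty result is allowed.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= missing_max <= 1.0):
        raise ValueError("missing_max must be in [0, 1]")
    keep = (panel.maf() > maf_min) & (panel.missing_rate() < missing_max)
    return panel.subset_variants(keep)


def filter_traits(traits: TraitMatrix, min_lines: int = 75) -> TraitMatrix:
    """Drop traits measured on fewer than ``min_lines`` lines."""
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    n = traits.n_lines_per_trait()
    keep = n.index[n >= min_lines]
    return TraitMatrix(traits.values[keep], traits.categories[keep])


def classify_region(
    variant: VariantRecord,
    inversions: Iterable[InversionDef],
    buffer_bp: int | None = None,
    known_arms: Iterable[str] | None = None,
) -> str:
    """Classify a position as inside / breakpoint_buffer / outside inversions.

    'inside' when ``start <= pos <= end`` for any inversion on the variant's
    arm; 'breakpoint_buffer' when within ``buffer_bp`` of either breakpoint
    but not inside; else 'outside'.  ``buffer_bp=None`` uses each
    inversion's own ``buffer_bp`` (default 2 Mb).
    """
    if known_arms is not None and variant.arm not in set(known_arms):
        raise ValueError(f"unknown arm {variant.arm!r}")
    in_buffer = False
    for inv in inversions:
        if inv.arm != variant.arm:
            continue
        if inv.start <= variant.pos <= inv.end:
            return "inside"
        buf = inv.buffer_bp if buffer_bp is None else buffer_bp
        d = min(abs(variant.pos - inv.start), abs(variant.pos - inv.end))
        if d <= buf:
            in_buffer = True
    return "breakpoint_buffer" if in_buffer else "outside"


def classify_regions(panel: GenotypePanel, inversions: Iterable[InversionDef], buffer_bp: int | None = None) -> np.ndarray:
    """Vector of region labels for every variant in the panel."""
    invs = list(inversions)
    return np.array(
        [
            classify_region(VariantRecord(r.id, r.arm, r.pos, r.ref, r.alt), invs, buffer_bp)
            for r in panel.variants.itertuples()
        ]
    )


# ---------------------------------------------------------------------------
# TSV I/O for the small tables
# ---------------------------------------------------------------------------

def read_karyotypes(path: str | Path) -> KaryotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return KaryotypeTable(df.where(df.notna(), np.nan))


def write_karyotypes(kt: KaryotypeTable, path: str | Path) -> None:
    kt.calls.to_csv(path, sep="\t", na_rep="NA", index_label="line_id")


def read_traits(path: str | Path, categories_path: str | Path | None = None) -> TraitMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cats = None
    if categories_path is not None:
        cdf = pd.read_csv(categories_path, sep="\t", index_col=0)
        cats = cdf.iloc[:, 0]
    return TraitMatrix(df, cats)


def write_traits(tm: TraitMatrix, path: str | Path, categories_path: str | Path | None = None) -> None:
    tm.values.to_csv(path, sep="\t", na_rep="NA", index_label="line_id")
    if categories_path is not None:
        tm.categories.rename("category").to_csv(categories_path, sep="\t", index_label="trait")


def read_inversions(path: str | Path, buffer_bp: int = 2_000_000) -> list[InversionDef]:
    df = pd.read_csv(path, sep="\t")
    return [
        InversionDef(r["name"], r["arm"], int(r["start"]), int(r["end"]), buffer_bp)
        for _, r in df.iterrows()
    ]


def write_inversions(invs: Sequence[InversionDef], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": i.name, "arm": i.arm, "start": i.start, "end": i.end} for i in invs]
    ).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> LineCovariates:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LineCovariates(df)


def write_covariates(cov: LineCovariates, path: str | Path) -> None:
    cov.table.to_csv(path, sep="\t", na_rep="NA", index_label="line_id")
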