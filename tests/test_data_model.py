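"""Containers, VCF/TSV round-trips, strict filters, region classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invgwas.data_model import (
    GenotypePanel,
    InversionDef,
    TraitMatrix,
    VariantRecord,
    classify_region,
    filter_traits,
    filter_variants,
    read_genotypes,
    write_genotypes,
)

from conftest import make_panel

VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=2L,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL0\tL1\tL2\tL3
2L\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t1/1\t0/0\t1/1
2L\t200\tv2\tC\tG\t.\t.\t.\tGT\t./.\t0/0\t0/0\t1/1
2L\t300\tv3\tA\tC,G\t.\t.\t.\tGT\t0/0\t0/0\t0/1\t0/2
"""


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestGenotypeIO:
    def test_vcf_dosage_and_maf(self, vcf_path):
        with pytest.warns(UserWarning, match="multi-allelic"):
            panel = read_genotypes(vcf_path, "vcf")
        assert panel.line_ids == ["L0", "L1", "L2", "L3"]
        assert panel.variants["id"].tolist() == ["v1", "v2"]  # multi-allelic rejected
        np.testing.assert_array_equal(panel.dosage[:, 0], [0, 2, 0, 2])
        assert panel.variants["maf"].iloc[0] == pytest.approx(0.5)

    def test_vcf_missing_rate(self, vcf_path):
        with pytest.warns(UserWarning):
            panel = read_genotypes(vcf_path, "vcf")
        assert panel.variants.set_index("id").loc["v2", "missing_rate"] == pytest.approx(0.25)

    @pytest.mark.parametrize("dialect", ["vcf", "tsv"])
    def test_round_trip_identity(self, tmp_path, dialect):
        rng = np.random.default_rng(0)
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(5, 12), p=[0.4, 0.1, 0.4, 0.1])
        panel = make_panel(dosage)
        out = tmp_path / f"rt.{dialect}"
        write_genotypes(panel, out, dialect)
        back = read_genotypes(out, dialect)
        np.testing.assert_array_equal(back.dosage, panel.dosage)
        assert back.line_ids == panel.line_ids
        pd.testing.assert_frame_equal(
            back.variants[["arm", "pos", "ref", "alt"]],
            panel.variants[["arm", "pos", "ref", "alt"]],
        )

    def test_duplicate_ids_rejected(self):
        meta = pd.DataFrame(
            {"id": ["a", "a"], "arm": "2L", "pos": [1, 2], "ref": "A", "alt": "T"}
        )
        with pytest.raises(ValueError, match="duplicate"):
            GenotypePanel(["L0"], meta, np.zeros((1, 2)))

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_genotypes("/nonexistent.vcf")


class TestFilterVariants:
    def test_strict_boundaries(self):
        # 10 lines; thresholds are strict, so maf == 0.05 and missing == 0.20
        # are both excluded while a clean variant survives
        d = np.zeros((10, 3))
        d[:2, 0] = 2  # v0: maf 0.2, no missing -> kept
        d[0, 1] = 1  # v1: maf exactly 0.05 (1 alt allele / 20) -> removed
        d[:2, 2] = 2  # v2: maf 0.2 but missing exactly 0.20 -> removed
        d[8:, 2] = np.nan
        panel = make_panel(d)
        kept = filter_variants(panel, maf_min=0.05, missing_max=0.20)
        assert kept.variants["id"].tolist() == [panel.variants["id"].iloc[0]]

    def test_maf_below_threshold_removed(self):
        d = np.zeros((25, 1))
        d[0, 0] = 2  # p = 0.04
        panel = make_panel(d)
        assert filter_variants(panel, 0.05, 0.2).n_variants == 0

    def test_brute_force_scan_oracle(self):
        rng = np.random.default_rng(42)
        d = rng.choice([0.0, 2.0, np.nan], size=(40, 10), p=[0.5, 0.4, 0.1])
        panel = make_panel(d)
        kept = filter_variants(panel, 0.1, 0.15)
        expected = []
        for j in range(10):
            col = d[:, j]
            obs = col[~np.isnan(col)]
            p = obs.sum() / (2 * len(obs))
            maf = min(p, 1 - p)
            miss = np.isnan(col).mean()
            if maf > 0.1 and miss < 0.15:
                expected.append(panel.variants["id"].iloc[j])
        assert kept.variants["id"].tolist() == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        d = rng.choice([0.0, 2.0, np.nan], size=(30, 15), p=[0.45, 0.45, 0.1])
        panel = make_panel(d)
        once = filter_variants(panel, 0.05, 0.2)
        twice = filter_variants(once, 0.05, 0.2)
        assert once.variants["id"].tolist() == twice.variants["id"].tolist()
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_maf_recomputed_after_line_subset(self):
        rng = np.random.default_rng(5)
        d = rng.choice([0.0, 2.0], size=(20, 8))
        panel = make_panel(d)
        sub = panel.subset_lines(panel.line_ids[:7])
        for j in range(8):
            col = d[:7, j]
            p = col.sum() / (2 * 7)
            assert sub.maf()[j] == pytest.approx(min(p, 1 - p))


class TestFilterTraits:
    def _matrix(self, n_obs_per_trait, n_lines=100):
        vals = {}
        for t, k in enumerate(n_obs_per_trait):
            col = np.full(n_lines, np.nan)
            col[:k] = 1.0 + t + np.arange(k) * 0.1
            vals[f"t{t}"] = col
        return TraitMatrix(pd.DataFrame(vals, index=[f"L{i}" for i in range(n_lines)]))

    def test_boundary_75(self):
        tm = self._matrix([74, 75, 76])
        kept = filter_traits(tm, min_lines=75)
        assert kept.trait_names == ["t1", "t2"]

    def test_min_lines_one_is_identity(self):
        tm = self._matrix([5, 30, 99])
        assert filter_traits(tm, 1).trait_names == tm.trait_names

    def test_hand_count_oracle(self):
        counts = [10, 74, 75, 80, 3]
        tm = self._matrix(counts)
        kept = filter_traits(tm, 75)
        assert kept.trait_names == [f"t{i}" for i, c in enumerate(counts) if c >= 75]


class TestClassifyRegion:
    INV = InversionDef("In(2L)t", "2L", 1_000_000, 2_000_000, buffer_bp=100_000)

    def _v(self, pos, arm="2L"):
        return VariantRecord("v", arm, pos, "A", "T")

    def test_inclusive_start(self):
        assert classify_region(self._v(1_000_000), [self.INV]) == "inside"

    def test_just_past_buffer(self):
        assert classify_region(self._v(2_100_001), [self.INV]) == "outside"

    def test_interval_oracle(self):
        positions = [500_000, 900_001, 1_000_000, 1_500_000, 2_000_000, 2_050_000, 2_100_000, 3_000_000]
        for pos in positions:
            got = classify_region(self._v(pos), [self.INV])
            if self.INV.start <= pos <= self.INV.end:
                want = "inside"
            elif (
                min(abs(pos - self.INV.start), abs(pos - self.INV.end)) <= self.INV.buffer_bp
            ):
                want = "breakpoint_buffer"
            else:
                want = "outside"
            assert got == want, pos

    def test_other_arm_is_outside(self):
        assert classify_region(self._v(1_500_000, arm="3R"), [self.INV]) == "outside"

    def test_unknown_arm_errors(self):
        with pytest.raises(ValueError, match="unknown arm"):
            classify_region(self._v(5, arm="4"), [self.INV], known_arms=["2L", "3R"])


@settings(max_examples=25, deadline=None)
@given(
    maf_min=st.floats(0.0, 0.5),
    missing_max=st.floats(0.0, 1.0),
    seed=st.integers(0, 1000),
)
def test_filter_variants_idempotent_property(maf_min, missing_max, seed):
    rng = np.random.default_rng(seed)
    d = rng.choice([0.0, 2.0, np.nan], size=(15, 8), p=[0.45, 0.45, 0.1])
    panel = make_panel(d)
    once = filter_variants(panel, maf_min, missing_max)
    twice = filter_variants(once, maf_min, missing_max)
    assert once.variants["id"].tolist() == twice.variants["id"].tolist()
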