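"""Quality-control filters: MAF, Hardy-Weinberg, call rate, marker density."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gpsel.genotypes import MISSING
from gpsel.qc import QCThresholds, filter_variants, hwe_exact_test, hwe_test, maf, snp_density
from gpsel.sim import corrupt_for_qc

from conftest import make_matrix


class TestMaf:
    def test_all_heterozygous_is_half(self):
        assert maf(np.ones(50, dtype=np.int8)) == 0.5

    def test_single_rare_allele(self):
        # 99 AA + 1 Aa: one copy of a in 200 alleles
        col = np.array([0] * 99 + [1], dtype=np.int8)
        assert maf(col) == pytest.approx(0.005)

    def test_symmetric_counts(self):
        col = np.array([0] * 30 + [1] * 40 + [2] * 30, dtype=np.int8)
        assert maf(col) == 0.5

    def test_missing_calls_excluded(self):
        col = np.array([0, 0, 2, MISSING, MISSING], dtype=np.int8)
        assert maf(col) == pytest.approx(2 / 6)

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            maf(np.full(5, MISSING, dtype=np.int8))


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_uniform_counts(self):
        # expected 7.5 / 15 / 7.5 -> chi-square 10/3
        p = hwe_test((10, 10, 10))
        assert p == pytest.approx(stats.chi2.sf(10 / 3, 1), rel=1e-12)
        assert p == pytest.approx(0.0679, abs=2e-4)

    def test_total_heterozygote_absence_fires_filter(self):
        assert hwe_test((50, 0, 50)) < 1e-6

    def test_monomorphic_convention(self):
        assert hwe_test((40, 0, 0)) == 1.0

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))

    def test_matches_first_principles_chi_square_exhaustively(self):
        """Brute-force oracle over every genotype-count triple with total <= 30."""
        for total in range(1, 31):
            for n_aa, n_ab in itertools.combinations_with_replacement(range(total + 1), 2):
                n_bb = total - n_aa - n_ab
                if n_bb < 0:
                    continue
                p = (2 * n_aa + n_ab) / (2 * total)
                if p in (0.0, 1.0):
                    assert hwe_test((n_aa, n_ab, n_bb)) == 1.0
                    continue
                exp = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2]) * total
                chi2 = float((((np.array([n_aa, n_ab, n_bb]) - exp) ** 2) / exp).sum())
                assert hwe_test((n_aa, n_ab, n_bb)) == pytest.approx(
                    float(stats.chi2.sf(chi2, 1)), rel=1e-10
                )

    def test_exact_test_agrees_with_chi_square_in_bulk(self):
        """The exact test and the chi-square approximation broadly agree for
        moderate counts away from the tails."""
        for counts in [(25, 50, 25), (40, 35, 25), (80, 15, 5)]:
            pe, pc = hwe_exact_test(counts), hwe_test(counts)
            assert (pe < 0.05) == (pc < 0.05) or abs(pe - pc) < 0.05


class TestFilterVariants:
    def test_clean_panel_passes_untouched(self, small_herd):
        genotypes, _, _ = small_herd
        filtered, report = filter_variants(genotypes)
        assert report.removed_call_rate == report.removed_hwe == report.removed_maf == 0
        assert report.removed_samples == 0
        assert filtered.n_snps == genotypes.n_snps

    def test_injected_corruption_is_recovered_exactly(self, small_herd):
        """Cross-module round trip: removal counts equal the injection manifest."""
        genotypes, _, _ = small_herd
        damaged, manifest = corrupt_for_qc(
            genotypes, missing_rate=0.15, n_low_call=10, n_low_maf=50, n_hwe_violating=5, seed=21
        )
        filtered, report = filter_variants(damaged)
        assert report.removed_call_rate == 10
        assert report.removed_hwe == 5
        assert report.removed_maf == 50
        assert set(report.removed_snp_ids["snp_call_rate"]) == set(
            manifest.loc[manifest["injection"] == "missing", "snp"]
        )
        assert set(report.removed_snp_ids["hwe"]) == set(
            manifest.loc[manifest["injection"] == "hwe", "snp"]
        )
        assert set(report.removed_snp_ids["maf"]) == set(
            manifest.loc[manifest["injection"] == "low_maf", "snp"]
        )
        # conservation per axis
        assert report.n_snps_retained + 65 == genotypes.n_snps
        assert report.n_samples_retained == genotypes.n_animals

    def test_filtering_is_idempotent(self, small_herd):
        genotypes, _, _ = small_herd
        damaged, _ = corrupt_for_qc(genotypes, seed=4)
        once, _ = filter_variants(damaged)
        twice, report = filter_variants(once)
        assert report.removed_call_rate == report.removed_hwe == report.removed_maf == 0
        assert report.removed_samples == 0
        assert np.array_equal(once.codes, twice.codes)

    def test_zero_maf_threshold_removes_only_monomorphic(self):
        codes = np.array([[0, 1, 2], [0, 1, 0], [0, 2, 1], [0, 0, 1]])
        gm = make_matrix(codes)
        filtered, report = filter_variants(gm, QCThresholds(min_maf=0.0))
        assert report.removed_maf == 1  # the all-zero column only
        assert filtered.n_snps == 2

    def test_all_markers_removed_is_an_explicit_error(self):
        gm = make_matrix(np.zeros((10, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="empty panel"):
            filter_variants(gm)

    def test_low_call_rate_samples_are_dropped(self, small_herd):
        genotypes, _, _ = small_herd
        codes = genotypes.codes.copy()
        codes[0, : int(0.2 * genotypes.n_snps)] = MISSING  # animal 0 at 80% call rate
        gm = make_matrix(codes)
        filtered, report = filter_variants(gm)
        assert report.removed_samples == 1
        assert filtered.n_animals == genotypes.n_animals - 1


class TestSnpDensity:
    def test_half_open_window_convention(self):
        markers = pd.DataFrame(
            {"chrom": [1, 1, 1], "snp": ["a", "b", "c"], "cm": 0.0, "bp": [1, 999_999, 1_000_000]}
        )
        out = snp_density(markers)
        counts = dict(zip(out["window"], out["count"]))
        assert counts == {0: 2, 1: 1}

    def test_toy_map_hand_tally(self):
        markers = pd.DataFrame(
            {
                "chrom": [1, 1, 1, 1, 2, 2, 2, 3, 3, 3],
                "snp": list("abcdefghij"),
                "cm": 0.0,
                "bp": [5, 10, 1_500_000, 2_000_001, 100, 2_500_000, 2_600_000, 999_999, 1_000_001, 3_141_592],
            }
        )
        out = snp_density(markers)
        assert out["count"].sum() == 10
        tally = {(r.chrom, r.window): r.count for r in out.itertuples()}
        assert tally == {(1, 0): 2, (1, 1): 1, (1, 2): 1, (2, 0): 1, (2, 2): 2,
                         (3, 0): 1, (3, 1): 1, (3, 3): 1}

    def test_unsorted_positions_rejected(self):
        markers = pd.DataFrame(
            {"chrom": [1, 1], "snp": ["a", "b"], "cm": 0.0, "bp": [200, 100]}
        )
        with pytest.raises(ValueError, match="increasing"):
            snp_density(markers)


def test_threshold_validation():
    with pytest.raises(ValueError):
        QCThresholds(min_call_rate_snp=1.5)
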