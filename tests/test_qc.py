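"""SNP filtering, chip concordance, missing rates, and LD decay."""

import numpy as np
import pandas as pd
import pytest

from ddgbs import (
    FilterConfig,
    SnpMatrix,
    concordance,
    filter_snps,
    ld_decay,
    missing_rates,
)
from ddgbs.qc import MISSING, pairwise_r2


def make_matrix(genotypes, chroms=None, positions=None, refs=None, alts=None,
                depth=None, gq=None, samples=None):
    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = gt.shape
    sites = pd.DataFrame(
        {
            "chrom": chroms or ["chr1"] * n_sites,
            "pos": positions or list(range(100, 100 + 10 * n_sites, 10)),
            "ref": refs or ["A"] * n_sites,
            "alt": alts or [("G",)] * n_sites,
        }
    )
    return SnpMatrix(
        sites=sites,
        genotypes=gt,
        samples=samples or [f"s{i}" for i in range(n_samples)],
        depth=None if depth is None else np.asarray(depth),
        gq=None if gq is None else np.asarray(gq),
    )


class TestFilterSnps:
    def _toy(self):
        # six sites x four samples:
        #  0: passes everything
        #  1: triallelic            -> dropped (biallelic_only)
        #  2: MAF 0.125 < 0.25      -> dropped (maf)
        #  3: low call rate         -> dropped (site_call_rate)
        #  4: low DP masks calls    -> call rate falls below threshold
        #  5: passes
        gt = [
            [0, 1, 1, 2],
            [0, 1, 0, 0],
            [0, 0, 0, 1],
            [0, MISSING, MISSING, MISSING],
            [0, 1, 1, 0],
            [2, 1, 0, 1],
        ]
        dp = np.full((6, 4), 10)
        dp[4, :3] = 2  # below dp_min -> masked, call rate 1/4
        gq = np.full((6, 4), 99)
        m = make_matrix(gt, depth=dp, gq=gq,
                        alts=[("G",), ("G", "T"), ("G",), ("G",), ("G",), ("G",)])
        cfg = FilterConfig(maf_min=0.25, gq_min=98, dp_min=5,
                           site_call_rate_min=0.6, sample_call_rate_min=0.01)
        return m, cfg

    def test_survivors_match_hand_filtered_toy(self):
        m, cfg = self._toy()
        out = filter_snps(m, cfg)
        assert list(out.sites["pos"]) == [100, 150]  # sites 0 and 5 survive

    def test_clean_matrix_is_unchanged(self):
        gt = [[0, 1, 2, 1], [1, 0, 1, 2]]
        m = make_matrix(gt, depth=np.full((2, 4), 30), gq=np.full((2, 4), 99))
        out = filter_snps(m, FilterConfig())
        assert out.n_sites == 2 and out.n_samples == 4
        assert (out.genotypes == m.genotypes).all()

    def test_filtering_is_idempotent(self):
        m, cfg = self._toy()
        once = filter_snps(m, cfg)
        twice = filter_snps(once, cfg)
        assert (once.genotypes == twice.genotypes).all()
        assert list(once.sites["pos"]) == list(twice.sites["pos"])
        assert once.samples == twice.samples

    def test_raising_dp_min_weakly_decreases_surviving_calls(self):
        m, _ = self._toy()
        survivors = []
        for dp_min in (0, 5, 8, 11):
            cfg = FilterConfig(maf_min=0.0, dp_min=dp_min, gq_min=0,
                               site_call_rate_min=0.0)
            out = filter_snps(m, cfg)
            survivors.append(int((out.genotypes != MISSING).sum()))
        assert survivors == sorted(survivors, reverse=True)

    def test_everything_removed_warns_and_returns_empty(self):
        m, _ = self._toy()
        with pytest.warns(UserWarning):
            out = filter_snps(m, FilterConfig(dp_min=11, site_call_rate_min=0.5))
        assert out.n_sites == 0

    def test_vcf_round_trip(self, tmp_path):
        m, cfg = self._toy()
        path = tmp_path / "calls.vcf"
        m.to_vcf(path)
        back = SnpMatrix.from_vcf(path)
        assert (back.genotypes == m.genotypes).all()
        assert (back.depth == m.depth).all()
        out = filter_snps(back, cfg)
        assert list(out.sites["pos"]) == [100, 150]


class TestConcordance:
    def test_identical_matrices_are_fully_concordant(self):
        gt = [[0, 1, 2], [1, 1, 0], [2, 0, 1]]
        gbs = make_matrix(gt, depth=np.full((3, 3), 30))
        chip = make_matrix(gt)
        report = concordance(gbs, chip, depth_thresholds=[2, 5, 12])
        assert (report.table["homozygous_pct"] == 100).all()
        assert (report.table["heterozygous_pct"] == 100).all()
        assert (report.table["total_pct"] == 100).all()

    def test_planted_het_error_hand_count(self):
        """10 chip-het and 10 chip-hom calls with one het->hom error:
        homo 100%, het 90%, call-weighted total 95%."""
        chip_gt = [[1] * 10, [0] * 10]
        gbs_gt = [[1] * 9 + [0], [0] * 10]
        chip = make_matrix(chip_gt, samples=[f"s{i}" for i in range(10)])
        gbs = make_matrix(gbs_gt, depth=np.full((2, 10), 30),
                          samples=[f"s{i}" for i in range(10)])
        report = concordance(gbs, chip, depth_thresholds=[5])
        row = report.table.iloc[0]
        assert row["homozygous_pct"] == 100.0
        assert row["heterozygous_pct"] == 90.0
        assert row["total_pct"] == 95.0
        assert row["n_compared"] == 20

    def test_ref_alt_swap_is_harmonized(self):
        gbs = make_matrix([[0, 1, 2]], refs=["A"], alts=[("G",)],
                          depth=np.full((1, 3), 30))
        chip = make_matrix([[2, 1, 0]], refs=["G"], alts=[("A",)])
        report = concordance(gbs, chip, depth_thresholds=[2])
        assert report.table["total_pct"].iloc[0] == 100.0

    def test_strand_ambiguous_sites_dropped_and_counted(self):
        gbs = make_matrix([[0, 1, 2], [0, 1, 2]],
                          refs=["A", "A"], alts=[("T",), ("G",)],
                          depth=np.full((2, 3), 30))
        chip = make_matrix([[0, 1, 2], [0, 1, 2]],
                           refs=["A", "A"], alts=[("T",), ("G",)])
        report = concordance(gbs, chip, depth_thresholds=[2])
        assert report.n_ambiguous_dropped == 1
        assert report.n_sites_matched == 1

    def test_depth_stratification_only_compares_deep_calls(self):
        gbs = make_matrix([[1, 1]], depth=np.array([[3, 10]]))
        chip = make_matrix([[1, 0]])
        report = concordance(gbs, chip, depth_thresholds=[2, 5])
        assert report.table.set_index("depth_threshold").loc[2, "n_compared"] == 2
        assert report.table.set_index("depth_threshold").loc[5, "n_compared"] == 1

    def test_no_shared_sites_rejected(self):
        gbs = make_matrix([[0, 1]], positions=[100],
                          depth=np.full((1, 2), 30))
        chip = make_matrix([[0, 1]], positions=[999])
        with pytest.raises(ValueError):
            concordance(gbs, chip)

    def test_het_consistency_nondecreasing_with_depth(self, sim_library):
        """Binomial allele sampling: deeper het calls are less likely to
        collapse to homozygous, so het concordance rises with the depth cut."""
        from ddgbs import simulate_chip, simulate_gbs_genotypes

        truth = sim_library["truth"]
        chip = simulate_chip(truth, 0.0, seed=1)
        gbs = simulate_gbs_genotypes(truth, mean_depth=6.0, seed=2,
                                     allele_sampling=True)
        report = concordance(gbs, chip, depth_thresholds=[2, 4, 6, 8])
        het = report.table["heterozygous_pct"].to_numpy()
        assert (np.diff(het) >= -1e-9).all()


class TestMissingRates:
    def test_complete_matrix_no_missing(self):
        m = make_matrix([[0, 1], [2, 0]], depth=np.full((2, 2), 10))
        rates = missing_rates(m, dp_min=0)
        assert (rates.per_site_before == 0).all()
        assert (rates.per_sample_after == 0).all()

    def test_hand_counted_masked_fractions(self):
        gt = np.zeros((4, 4), dtype=np.int8)
        dp = np.full((4, 4), 10)
        dp[0, 0] = dp[1, 1] = dp[1, 2] = 2  # three calls below 5x
        rates = missing_rates(make_matrix(gt, depth=dp), dp_min=5)
        assert rates.per_site_before.sum() == 0
        assert rates.per_site_after.tolist() == [0.25, 0.5, 0.0, 0.0]
        assert rates.per_sample_after.tolist() == [0.25, 0.25, 0.25, 0.0]

    def test_site_and_sample_means_agree(self, sim_library):
        from ddgbs import simulate_gbs_genotypes

        gbs = simulate_gbs_genotypes(sim_library["truth"], mean_depth=3.0,
                                     seed=5)
        rates = missing_rates(gbs, dp_min=5)
        assert rates.per_site_after.mean() == pytest.approx(
            rates.per_sample_after.mean()
        )


class TestLdDecay:
    def test_duplicated_site_has_full_r2(self):
        gt = [[0, 1, 1, 2], [0, 1, 1, 2]]
        m = make_matrix(gt, positions=[100, 200])
        decay = ld_decay(m, max_distance=1000, bins=2)
        assert decay.mean_r2[np.isfinite(decay.mean_r2)][0] == pytest.approx(1.0)

    def test_hand_computed_dosage_correlation(self):
        a, b = np.array([0, 1, 1, 2.0]), np.array([0, 1, 2, 2.0])
        assert pairwise_r2(a, b) == pytest.approx(8 / 11)

    def test_independent_sites_have_near_zero_r2(self):
        rng = np.random.default_rng(1)
        gt = rng.binomial(2, 0.5, size=(2, 10_000)).astype(np.int8)
        m = make_matrix(gt, positions=[100, 200],
                        samples=[f"s{i}" for i in range(10_000)])
        decay = ld_decay(m, max_distance=1000, bins=1)
        assert decay.mean_r2[0] < 0.01

    def test_r2_symmetric_and_allele_swap_invariant(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.3, size=50).astype(float)
        b = rng.binomial(2, 0.4, size=50).astype(float)
        assert pairwise_r2(a, b) == pytest.approx(pairwise_r2(b, a))
        assert pairwise_r2(2 - a, b) == pytest.approx(pairwise_r2(a, b))

    def test_monomorphic_pairs_excluded(self):
        gt = [[0, 0, 0, 0], [0, 1, 1, 2]]
        m = make_matrix(gt, positions=[100, 200])
        decay = ld_decay(m, max_distance=1000, bins=2)
        assert decay.n_pairs_excluded == 1

    def test_decay_distance_found_on_synthetic_block_structure(self):
        """Sites inside a tight block stay correlated; distant pairs are
        independent, so the mean r2 falls below threshold at long range."""
        rng = np.random.default_rng(3)
        n = 400
        block = rng.binomial(2, 0.5, size=n).astype(np.int8)
        far = rng.binomial(2, 0.5, size=(3, n)).astype(np.int8)
        gt = np.vstack([block, block, far])
        m = make_matrix(gt, positions=[100, 150, 5000, 9000, 9900],
                        samples=[f"s{i}" for i in range(n)])
        decay = ld_decay(m, max_distance=10_000, bins=10, threshold=0.1)
        assert decay.decay_distance is not None
        assert decay.decay_distance > 150
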