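"""Binning, the variation-reduction cascade, Z-score standardisation and
the cross-validation / threshold-sweep machinery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from smashnipt import aneuploidy, simkit
from smashnipt.aneuploidy import BinMatrix


def make_matrix(counts, gc=None, chroms=None, state="raw"):
    counts = np.asarray(counts, dtype=float)
    n_bins = counts.shape[1]
    bins = pd.DataFrame({
        "chrom": chroms if chroms is not None else ["chr1"] * n_bins,
        "start": np.arange(n_bins) * 1000,
        "end": (np.arange(n_bins) + 1) * 1000,
        "gc": gc if gc is not None else np.full(n_bins, 0.4),
    })
    return BinMatrix(bins, counts,
                     [f"s{i}" for i in range(counts.shape[0])], state)


class TestBinning:
    def test_single_fragment_lands_in_containing_bin(self, toy_reference):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [144]})
        bm = aneuploidy.bin_counts(frags, 10_000, toy_reference)
        first_chr1 = (bm.bins["chrom"] == "chr1") & (bm.bins["start"] == 0)
        assert bm.counts[0, first_chr1.to_numpy()] == 1
        assert bm.counts.sum() == 1

    def test_counts_conserved_and_multinomial_uniform(self, toy_reference):
        rng = np.random.default_rng(0)
        n = 100_000
        L = toy_reference.chrom_lengths["chr1"]
        frags = pd.DataFrame({"chrom": "chr1",
                              "start": rng.integers(0, L, n),
                              "end": rng.integers(0, L, n) + 44})
        bin_size = L // 20
        bm = aneuploidy.bin_counts(frags, bin_size, toy_reference)
        assert bm.counts.sum() == n
        chr1 = (bm.bins["chrom"] == "chr1").to_numpy()
        full_bins = chr1 & ((bm.bins["end"] - bm.bins["start"]) == bin_size).to_numpy()
        expected = n * bin_size / L
        assert np.all(np.abs(bm.counts[0, full_bins] - expected)
                      < 4 * np.sqrt(expected))

    def test_fragment_beyond_chromosome_end_rejected(self, toy_reference):
        L = toy_reference.chrom_lengths["chr1"]
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [L + 5], "end": [L + 49]})
        with pytest.raises(ValueError, match="beyond chromosome end"):
            aneuploidy.bin_counts(frags, 10_000, toy_reference)


class TestPeakCorrection:
    def test_single_peak_reset_to_mean(self):
        counts = np.full((1, 100), 100.0)
        counts[0, 7] = 1000.0
        out = aneuploidy.peak_correction(make_matrix(counts))
        assert out.counts[0, 7] == pytest.approx(counts[0].mean())
        assert out.state == "peak_corrected"

    def test_flat_profile_unchanged(self):
        counts = np.full((2, 50), 42.0)
        out = aneuploidy.peak_correction(make_matrix(counts))
        assert np.array_equal(out.counts, counts)

    def test_total_never_increases_when_peak_removed(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.poisson(100, (1, 200)).astype(float)
            counts[0, rng.integers(200)] *= 20
            out = aneuploidy.peak_correction(make_matrix(counts))
            assert out.counts.sum() <= counts.sum()

    def test_requires_raw_state(self):
        m = make_matrix(np.ones((1, 10)), state="gc_corrected")
        with pytest.raises(ValueError, match="correction order"):
            aneuploidy.peak_correction(m)


class TestGcCorrection:
    def test_uniform_gc_is_identity(self):
        counts = np.arange(1, 41, dtype=float)[None, :]
        m = aneuploidy.peak_correction(make_matrix(counts))
        out = aneuploidy.gc_correct(m)
        assert np.allclose(out.counts, m.counts)

    def test_two_strata_normalised_to_common_mean(self):
        gc = np.array([0.30] * 20 + [0.50] * 20)
        counts = np.array([[100.0] * 20 + [200.0] * 20])
        m = make_matrix(counts, gc=gc, state="peak_corrected")
        out = aneuploidy.gc_correct(m)
        assert np.allclose(out.counts, 150.0)

    def test_small_strata_left_uncorrected(self):
        gc = np.array([0.30] * 5 + [0.50] * 20)  # first stratum < 10 bins
        counts = np.array([[100.0] * 5 + [200.0] * 20])
        out = aneuploidy.gc_correct(make_matrix(counts, gc=gc,
                                                state="peak_corrected"))
        assert np.allclose(out.counts[0, :5], 100.0)

    def test_corrected_strata_hit_global_mean(self):
        rng = np.random.default_rng(2)
        gc = np.round(rng.choice([0.35, 0.45, 0.55], 300), 2)
        counts = rng.poisson(100 + 200 * gc, (1, 300)).astype(float)
        m = make_matrix(counts, gc=gc, state="peak_corrected")
        out = aneuploidy.gc_correct(m)
        global_mean = out.counts[0].mean()
        for g in np.unique(gc):
            assert out.counts[0, gc == g].mean() == pytest.approx(global_mean,
                                                                  rel=1e-6)


class TestChi2Correction:
    def test_identical_controls_are_identity(self):
        counts = np.tile(np.arange(1, 31, dtype=float), (4, 1))
        m = make_matrix(counts, state="gc_corrected")
        out = aneuploidy.chi2_variation_reduction(m, m)
        assert np.allclose(out.counts, counts)
        assert out.state == "chi2_corrected"

    def test_hand_computed_statistic_on_four_controls(self):
        """Half the controls at 2c, half at 0 in one bin: reduced chi2 =
        N*c/(N-1); the bin is damped by exactly that factor."""
        base = np.full((4, 30), 100.0)
        base[:, 3] = [200.0, 200.0, 0.0, 0.0]
        base[:, 4] = [0.0, 0.0, 200.0, 200.0]  # keeps totals equal
        m = make_matrix(base, state="gc_corrected")
        out = aneuploidy.chi2_variation_reduction(m, m, reduced_chi2_cutoff=3.5)
        red = 4 * 100.0 / 3
        assert out.counts[0, 3] == pytest.approx(200.0 / red)
        assert out.counts[2, 3] == pytest.approx(0.0)
        assert np.allclose(out.counts[:, 5:], 100.0)

    def test_zero_mean_bin_masked_everywhere(self):
        counts = np.full((3, 20), 50.0)
        counts[:, 11] = 0.0
        m = make_matrix(counts, state="gc_corrected")
        out = aneuploidy.chi2_variation_reduction(m, m)
        assert not out.mask[11]
        fr = aneuploidy.chromosomal_fraction(out, "chr1")
        # masked bin excluded from numerator and denominator for everyone
        assert np.allclose(fr, fr[0])

    def test_requires_two_controls(self):
        m = make_matrix(np.ones((1, 10)), state="gc_corrected")
        with pytest.raises(ValueError, match="2 control"):
            aneuploidy.chi2_variation_reduction(m, m)


class TestMatchQc:
    def test_sample_at_control_mean_scores_zero(self):
        ctrl = make_matrix(np.tile([10.0, 20.0, 30.0, 40.0], (4, 1)))
        res = aneuploidy.match_qc(np.array([10.0, 20.0, 30.0, 40.0]), ctrl)
        assert res.score == 0.0 and res.passed

    def test_permuted_profile_scores_positive(self):
        rng = np.random.default_rng(3)
        profile = rng.poisson(100, 50).astype(float)
        ctrl = make_matrix(np.tile(profile, (5, 1)))
        res = aneuploidy.match_qc(rng.permutation(profile), ctrl)
        assert res.score > 0

    def test_controls_pass_their_own_leave_one_out_qc(self):
        rng = np.random.default_rng(4)
        passes = 0
        n_fixtures = 50
        for _ in range(n_fixtures):
            counts = rng.poisson(200, (8, 100)).astype(float)
            ctrl = make_matrix(counts)
            i = rng.integers(8)
            rest = make_matrix(np.delete(counts, i, axis=0))
            passes += aneuploidy.match_qc(counts[i], rest).passed
        assert passes / n_fixtures >= 0.9

    def test_too_few_controls_skips_with_warning(self):
        ctrl = make_matrix(np.ones((2, 10)))
        with pytest.warns(UserWarning, match="match QC skipped"):
            res = aneuploidy.match_qc(np.ones(10), ctrl)
        assert res.note is not None


class TestChromosomalFraction:
    def test_target_share_of_denominator(self):
        chroms = ["chr21"] * 2 + ["chr1"] * 18
        counts = np.array([[5.0, 5.0] + [5.0] * 18])
        m = make_matrix(counts, chroms=chroms, state="chi2_corrected")
        fr = aneuploidy.chromosomal_fraction(m, "chr21")
        assert fr[0] == pytest.approx(10.0 / 90.0)

    def test_excluded_chromosomes_not_in_denominator(self):
        chroms = ["chr21", "chr18", "chr13", "chrX", "chrY", "chr1", "chr2"]
        counts = np.array([[10.0, 99.0, 99.0, 99.0, 99.0, 40.0, 60.0]])
        m = make_matrix(counts, chroms=chroms, state="chi2_corrected")
        assert aneuploidy.chromosomal_fraction(m, "chr21")[0] == \
            pytest.approx(10.0 / 100.0)

    def test_zero_denominator_raises(self):
        m = make_matrix(np.array([[7.0]]), chroms=["chr21"],
                        state="chi2_corrected")
        with pytest.raises(ValueError, match="denominator"):
            aneuploidy.chromosomal_fraction(m, "chr21")


class TestZScore:
    def test_boundary_is_euploid_at_exactly_three_sigma(self):
        ctrl = np.array([0.9, 1.0, 1.1, 1.0, 0.95, 1.05])
        mean, sd = ctrl.mean(), ctrl.std(ddof=1)
        res = aneuploidy.z_score(mean + 3 * sd, ctrl)
        assert res.z == pytest.approx(3.0)
        assert res.call == "euploid"  # strict >
        assert aneuploidy.z_score(mean + 3.01 * sd, ctrl).call == "aneuploid"

    def test_sample_at_mean_scores_zero(self):
        ctrl = np.array([1.0, 2.0, 3.0])
        assert aneuploidy.z_score(2.0, ctrl).z == 0.0

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            aneuploidy.z_score(1.0, np.array([1.0, 1.0, 1.0]))

    def test_leave_one_out_standardisation(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(0.017, 0.0001, 200)
        zs = [aneuploidy.z_score(ctrl[i], np.delete(ctrl, i)).z
              for i in range(len(ctrl))]
        assert abs(np.mean(zs)) < 0.1
        assert 0.9 < np.std(zs, ddof=1) < 1.15


class TestCrossValidation:
    def test_perfect_separation_gives_unit_metrics(self):
        fr = np.concatenate([np.random.default_rng(6).normal(1.0, 0.01, 20),
                             np.full(5, 2.0)])
        labels = np.array([False] * 20 + [True] * 5)
        cv = aneuploidy.cross_validate(fr, labels, n_runs=50, seed=1)
        assert cv.sensitivity == 1.0 and cv.sensitivity_sd == 0.0
        assert cv.specificity == 1.0 and cv.auc == 1.0

    def test_split_sizes_for_25_cases_48_controls(self):
        rng = np.random.default_rng(7)
        fr = np.concatenate([rng.normal(0, 1, 48), rng.normal(5, 1, 25)])
        labels = np.array([False] * 48 + [True] * 25)
        cv = aneuploidy.cross_validate(fr, labels, n_runs=5, seed=2)
        assert cv.n_test == 50
        assert cv.n_train == 23

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        fr = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 6)])
        labels = np.array([False] * 30 + [True] * 6)
        a = aneuploidy.cross_validate(fr, labels, n_runs=40, seed=9)
        b = aneuploidy.cross_validate(fr, labels, n_runs=40, seed=9)
        assert (a.sensitivity, a.specificity, a.auc) == \
            (b.sensitivity, b.specificity, b.auc)
        assert np.array_equal(a.z_min, b.z_min)

    def test_requires_more_controls_than_cases(self):
        fr = np.arange(10.0)
        labels = np.array([True] * 5 + [False] * 5)
        with pytest.raises(ValueError, match="more controls"):
            aneuploidy.cross_validate(fr, labels)

    def test_auc_matches_brute_force_pairwise_count(self):
        rng = np.random.default_rng(10)
        cases = rng.normal(1, 1, 30)
        ctrls = rng.normal(0, 1, 40)
        brute = np.mean([(c > d) + 0.5 * (c == d)
                         for c in cases for d in ctrls])
        assert aneuploidy._auc(cases, ctrls) == pytest.approx(brute)


class TestSweep:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(11)
        n_ctrl, n_case = 40, 8
        return pd.DataFrame({
            "fraction": np.concatenate([rng.normal(0.0175, 1e-4, n_ctrl),
                                        rng.normal(0.0184, 1e-4, n_case)]),
            "label": [False] * n_ctrl + [True] * n_case,
            "n_filtered": rng.integers(800_000, 3_500_000, n_ctrl + n_case),
        })

    def test_default_thresholds_are_the_published_grid(self):
        assert list(aneuploidy.DEFAULT_SWEEP_THRESHOLDS) == \
            [1_000_000, 1_500_000, 2_000_000, 2_500_000, 3_000_000]

    def test_qualifying_counts_monotone_in_threshold(self, cohort):
        tab = aneuploidy.min_fragment_sweep({"chr21": cohort}, n_runs=10, seed=3)
        counts = (tab["n_cases"] + tab["n_controls"]).to_numpy()
        assert np.all(np.diff(counts) <= 0)
        assert len(tab) == 5

    def test_empty_cell_reported_as_undefined(self, cohort):
        cohort.loc[cohort["label"], "n_filtered"] = 900_000  # no cases pass 1M
        tab = aneuploidy.min_fragment_sweep({"chr21": cohort}, n_runs=5, seed=4)
        high = tab[tab["threshold"] >= 1_000_000]
        assert high["sensitivity"].isna().all()


class TestDosageLink:
    def test_expected_z_grows_with_fetal_fraction(self, toy_reference, toy_config):
        """The trisomy shift is ff/2, so E[z] should rise roughly linearly
        over the ff grid."""
        rng = np.random.default_rng(12)
        bin_size = toy_reference.genome_length // 500
        bins = aneuploidy.make_bins(toy_reference, bin_size)

        def fraction(ff, trisomy, n=400_000):
            cfg = dataclasses.replace(
                toy_config, fetal_fraction=ff,
                trisomy_chrom="chr21" if trisomy else None)
            frags = simkit.simulate_cfdna(toy_reference, cfg, n=n, rng=rng)
            bm = aneuploidy.bin_counts(frags, bin_size, toy_reference, bins=bins)
            bm.state = "chi2_corrected"
            return aneuploidy.chromosomal_fraction(bm, "chr21")[0]

        ctrl = np.array([fraction(0.10, False) for _ in range(12)])
        zs = {ff: aneuploidy.z_score(fraction(ff, True), ctrl).z
              for ff in (0.04, 0.08, 0.12)}
        assert zs[0.04] < zs[0.08] < zs[0.12]
        # slope check: z at ff=0.12 is ~3x z at ff=0.04, generously banded
        assert 1.7 < zs[0.12] / zs[0.04] < 4.5
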