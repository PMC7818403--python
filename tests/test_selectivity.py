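"""Single-voxel dAction/dBall selectivity, shuffle null, group analyses."""

import numpy as np
import pytest
from scipy import stats

from numact.bold import EffectSizes, make_population, simulate_psc_runs
from numact.recoding import recode_all
from numact.selectivity import (compute_scatter, group_prop_analysis,
                                group_prop_report, paired_t_voxels,
                                pairwise_chi2, prop_below_diagonal,
                                sd_distance, selectivity_summary,
                                shuffle_null)


class TestScatter:
    def test_single_subject_arithmetic(self):
        vals = [np.array([[1.0, 0.2, 0.5, 0.4]])]
        pts = compute_scatter(vals, "group_average")
        assert pts[0] == pytest.approx([0.8, 0.1])

    def test_group_average_equals_differencing_voxel_means(self, rng):
        a, b = rng.normal(size=(2, 9, 4))
        pts = compute_scatter([a, b], "group_average")
        m = (a + b) / 2
        assert np.allclose(pts[:, 0], m[:, 0] - m[:, 1])
        assert np.allclose(pts[:, 1], m[:, 2] - m[:, 3])

    def test_per_subject_mode_shape(self, rng):
        vals = [rng.normal(size=(5, 4)) for _ in range(3)]
        pts = compute_scatter(vals, "per_subject")
        assert pts.shape == (3, 5, 2)

    def test_action_selective_population_lands_below_diagonal(self):
        """With a strongly action-tuned population at high SNR, the recoded
        group scatter concentrates below the diagonal."""
        eff = EffectSizes(delta_action=1.0, noise_sd=0.0)
        pop = make_population("NPC3_L", (0.8, 0.0, 0.1, 0.1), n_voxels=200,
                              effects=eff, seed=1)
        recs = [recode_all(simulate_psc_runs(pop, 9, 0.3, seed=10 + s),
                           k=3, seed=s) for s in range(4)]
        pts = compute_scatter(recs, "group_average")
        assert prop_below_diagonal(pts) > 70


class TestPropBelow:
    def test_all_below_and_mirror_complement(self, rng):
        d = np.abs(rng.normal(size=50)) + 0.1
        pts = np.column_stack([d, np.zeros(50)])
        assert prop_below_diagonal(pts) == 100.0
        mirrored = pts[:, ::-1]
        assert prop_below_diagonal(mirrored) == 0.0
        mixed = np.vstack([pts, pts[:, ::-1]])
        assert prop_below_diagonal(mixed) == 50.0

    def test_null_population_near_fifty(self):
        pop = make_population("NPC3_L", (0, 0, 0, 1), n_voxels=400, seed=2)
        recs = [recode_all(simulate_psc_runs(pop, 9, 1.0, seed=20 + s),
                           k=3, seed=s) for s in range(3)]
        p = prop_below_diagonal(compute_scatter(recs, "group_average"))
        se = 100 * np.sqrt(0.25 / 400)
        assert abs(p - 50) < 4 * se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prop_below_diagonal(np.empty((0, 2)))


class TestPairedT:
    def test_df_matches_voxel_count(self, rng):
        pts = rng.normal(size=(449, 2))
        t, df, p = paired_t_voxels(pts)
        assert df == 448

    def test_symmetric_pairs_give_zero_t(self):
        d = np.array([0.5, -0.5, 0.25, -0.25])
        pts = np.column_stack([d, np.zeros(4)])
        t, _, _ = paired_t_voxels(pts)
        assert t == pytest.approx(0.0)

    def test_matches_formula_oracle(self, rng):
        pts = rng.normal(size=(100, 2))
        d = pts[:, 0] - pts[:, 1]
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_ref), len(d) - 1)
        t, df, p = paired_t_voxels(pts)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestChi2:
    def test_equal_proportions_give_zero(self):
        chi2, p = pairwise_chi2(50.0, 200, 50.0, 200)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_pearson_formula_on_random_tables(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(20, 500, size=2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            chi2, _ = pairwise_chi2(100 * k1 / n1, n1, 100 * k2 / n2, n2)
            obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
            exp = obs.sum(1, keepdims=True) * obs.sum(0) / obs.sum()
            ref = ((obs - exp) ** 2 / exp).sum()
            assert chi2 == pytest.approx(ref, abs=1e-10)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            pairwise_chi2(0.0, 100, 0.0, 100)


class TestShuffleNull:
    def test_mean_at_chance_for_arbitrary_data(self, rng):
        vals = [rng.normal(size=(97, 4)) + rng.normal(size=4)
                for _ in range(5)]
        null = shuffle_null(vals, n_shuffles=4000, seed=3)
        assert abs(null.mean - 50.0) < 0.5
        assert null.probabilities.sum() == pytest.approx(1.0)

    def test_sd_follows_binomial_scaling(self, rng):
        """Null SD ~ 100 sqrt(0.25/N): SD * sqrt(N) constant within 10%."""
        consts = []
        for n_vox in (86, 203, 449):
            vals = [rng.normal(size=(n_vox, 4)) for _ in range(3)]
            null = shuffle_null(vals, n_shuffles=4000, seed=4)
            consts.append(null.sd * np.sqrt(n_vox))
        assert max(consts) / min(consts) < 1.1
        assert consts[1] == pytest.approx(100 * np.sqrt(0.25), rel=0.1)

    def test_per_subject_distributions_approximately_normal(self, rng):
        """At N >= 86 voxels the per-subject shuffled distributions are
        close to normal (small skewness and excess kurtosis)."""
        vals = [rng.normal(size=(86, 4)) for _ in range(3)]
        null = shuffle_null(vals, n_shuffles=5000, seed=5,
                            keep_subject_props=True)
        for props in null.subject_props:
            assert abs(stats.skew(props)) < 0.2
            assert abs(stats.kurtosis(props)) < 0.3

    def test_full_permutation_scheme_also_centred(self, rng):
        vals = [rng.normal(size=(60, 4)) for _ in range(2)]
        null = shuffle_null(vals, n_shuffles=2000, seed=6,
                            scheme="full_permutation")
        assert abs(null.mean - 50.0) < 1.5

    def test_seed_reproducibility(self, rng):
        vals = [rng.normal(size=(40, 4))]
        a = shuffle_null(vals, n_shuffles=500, seed=7)
        b = shuffle_null(vals, n_shuffles=500, seed=7)
        assert np.array_equal(a.probabilities, b.probabilities)


class TestSdDistance:
    def test_observed_at_mean_is_zero(self):
        assert sd_distance(50.0, (50.0, 3.0)) == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            sd_distance(60.0, (50.0, 0.0))


class TestGroupAnalysis:
    def test_all_subjects_at_fifty_give_zero_t(self):
        # 2 of 4 voxels below the diagonal for every subject
        arr = np.array([[1.0, 0.0, 0.0, 0.0],
                        [1.0, 0.0, 0.0, 0.0],
                        [0.0, 0.0, 1.0, 0.0],
                        [0.0, 0.0, 1.0, 0.0]])
        recs = [arr.copy() for _ in range(5)]
        df = group_prop_report({"ROI": recs}, reference_roi="ROI")
        assert df["mean"].iloc[0] == pytest.approx(50.0)
        assert df["t_vs_50"].iloc[0] == pytest.approx(0.0)

    def test_df_is_subjects_minus_one(self, rng):
        recs = {r: [rng.normal(size=(30, 4)) for _ in range(21)]
                for r in ("A", "B")}
        df = group_prop_report(recs, reference_roi="A")
        assert df["df"].eq(20).all()
        assert np.isnan(df.loc[df.roi == "A", "paired_t_vs_ref"]).all()
        assert np.isfinite(df.loc[df.roi == "B", "paired_t_vs_ref"]).all()

    def test_refined_variant_reduces_subject_variance(self):
        """Averaging the below-diagonal proportion over cross-validation
        replications shrinks the across-subject spread."""
        eff = EffectSizes(delta_action=0.3)
        pop = make_population("NPC3_L", (0.5, 0.2, 0.2, 0.1), n_voxels=80,
                              effects=eff, seed=8)
        recs = [recode_all(simulate_psc_runs(pop, 9, 1.2, seed=30 + s),
                           k=3, seed=s, keep_replications=True)
                for s in range(12)]
        standard = group_prop_analysis(recs, refined=False)
        refined = group_prop_analysis(recs, refined=True)
        assert refined.std(ddof=1) < standard.std(ddof=1)

    def test_refined_requires_replications(self, rng):
        rec = recode_all(rng.normal(size=(5, 9, 4)), k=3, seed=0,
                         keep_replications=False)
        with pytest.raises(ValueError):
            group_prop_analysis([rec], refined=True)


class TestRecoveryMonotonicity:
    def test_prop_below_grows_with_action_selective_fraction(self):
        props = []
        for i, frac in enumerate((0.0, 0.4, 0.8)):
            mixture = (frac, 0.0, 0.2, 0.8 - frac)
            pop = make_population("NPC3_L", mixture, n_voxels=300,
                                  effects=EffectSizes(delta_action=0.6),
                                  seed=40 + i)
            recs = [recode_all(simulate_psc_runs(pop, 9, 0.8,
                                                 seed=50 + 10 * i + s),
                               k=3, seed=s) for s in range(5)]
            props.append(prop_below_diagonal(
                compute_scatter(recs, "group_average")))
        assert props[0] == pytest.approx(50, abs=4 * 100 * np.sqrt(0.25 / 300))
        assert props[0] < props[1] < props[2]


class TestSummaryTable:
    def test_summary_columns_and_reference(self, rng):
        recs = {r: [rng.normal(size=(40, 4)) for _ in range(4)]
                for r in ("NPC3_L", "OTS_L")}
        df = selectivity_summary(recs, reference_roi="NPC3_L")
        assert set(df.columns) >= {"roi", "n_voxels", "prop_below", "t",
                                   "df", "p", "chi2_vs_ref"}
        assert np.isnan(
            df.loc[df.roi == "NPC3_L", "chi2_vs_ref"].iloc[0])
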