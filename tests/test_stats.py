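"""Size ANOVA, allometry regression, disparity and observer repeatability."""

import numpy as np
import pytest
from scipy.stats import f_oneway

from wingmorph import (
    Sex,
    Species,
    SyntheticSpec,
    allometry_regression,
    generate_study,
    gpa,
    morphological_disparity,
    observer_repeatability,
    observer_size_effect,
    size_anova,
)


class TestSizeAnova:
    def test_identical_groups_give_zero_f(self):
        sizes = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = ["a"] * 3 + ["b"] * 3
        res = size_anova(sizes, groups)
        assert res.statistic_F == 0.0
        assert res.parametric_p == 1.0

    def test_degrees_of_freedom_for_two_group_study(self, rng):
        # 77 + 67 female specimens -> F on (1, 142) degrees of freedom
        sizes = rng.lognormal(7.0, 0.05, size=144)
        groups = ["japonicus"] * 77 + ["koreicus"] * 67
        res = size_anova(sizes, groups)
        assert (res.df_model, res.df_resid) == (1, 142)

    @pytest.mark.parametrize("sizes_per_group", [(30, 25), (20, 20, 20)])
    def test_f_matches_independent_oracle(self, rng, sizes_per_group):
        samples = [rng.lognormal(0.0, 0.3, size=n) for n in sizes_per_group]
        sizes = np.concatenate(samples)
        groups = np.repeat(np.arange(len(sizes_per_group)), sizes_per_group)
        res = size_anova(sizes, groups)
        oracle = f_oneway(*samples)
        assert res.statistic_F == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.parametric_p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_permutation_p_floor_and_reproducibility(self, rng):
        sizes = rng.lognormal(0.0, 0.1, size=40)
        groups = np.repeat(["a", "b"], 20)
        r1 = size_anova(sizes, groups, n_permutations=99, seed=5)
        r2 = size_anova(sizes, groups, n_permutations=99, seed=5)
        assert r1.p_value == r2.p_value and r1.z_score == r2.z_score
        assert r1.p_value >= 1.0 / 100.0

    def test_parametric_and_permutation_p_agree_for_normal_data(self, rng):
        sizes = np.concatenate(
            [rng.normal(10.0, 1.0, 120), rng.normal(10.25, 1.0, 120)]
        )
        groups = np.repeat(["a", "b"], 120)
        res = size_anova(sizes, groups, n_permutations=10_000, seed=9)
        assert abs(res.p_value - res.parametric_p) < 0.02

    def test_errors(self):
        with pytest.raises(ValueError, match="two levels"):
            size_anova(np.ones(4) + np.arange(4), ["a"] * 4)
        with pytest.raises(ValueError, match="at least two specimens"):
            size_anova(np.array([1.0, 2.0, 3.0]), ["a", "a", "b"])
        with pytest.raises(ValueError, match="positive"):
            size_anova(np.array([1.0, -2.0, 3.0, 4.0]), ["a", "a", "b", "b"])


class TestAllometryRegression:
    def test_perfectly_allometric_shapes(self, rng):
        n, p = 40, 36
        u = rng.standard_normal(p)
        u /= np.linalg.norm(u)
        sizes = rng.lognormal(7.0, 0.1, size=n)
        shapes = np.ones(p) + 0.01 * np.outer(sizes, u)
        res = allometry_regression(shapes, sizes, n_permutations=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degrees_of_freedom_male_sample(self, rng):
        shapes = rng.standard_normal((127, 36))
        sizes = rng.lognormal(7.0, 0.05, size=127)
        res = allometry_regression(shapes, sizes, n_permutations=0)
        assert (res.df_model, res.df_resid) == (1, 125)

    def test_r2_invariant_to_affine_size_rescaling(self, rng):
        shapes = rng.standard_normal((50, 36))
        sizes = rng.lognormal(7.0, 0.1, size=50)
        r1 = allometry_regression(shapes, sizes, n_permutations=0)
        r2 = allometry_regression(shapes, 3.7 * sizes + 11.0, n_permutations=0)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-12)
        assert r1.statistic_F == pytest.approx(r2.statistic_F, abs=1e-9)

    def test_f_matches_column_wise_ols_oracle(self, rng):
        # brute-force oracle: per-column simple least squares fits
        n, p = 30, 10
        shapes = rng.standard_normal((n, p))
        sizes = rng.lognormal(0.0, 0.2, size=n)
        x = np.column_stack([np.ones(n), sizes])
        ss_model = 0.0
        ss_total = 0.0
        for j in range(p):
            y = shapes[:, j]
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            fitted = x @ beta
            ss_model += np.sum((fitted - y.mean()) ** 2)
            ss_total += np.sum((y - y.mean()) ** 2)
        f_oracle = (ss_model / 1) / ((ss_total - ss_model) / (n - 2))
        res = allometry_regression(shapes, sizes, n_permutations=0)
        assert res.statistic_F == pytest.approx(f_oracle, rel=1e-10)
        assert res.r_squared == pytest.approx(ss_model / ss_total, rel=1e-10)

    def test_constant_sizes_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            allometry_regression(
                rng.standard_normal((10, 4)), np.full(10, 2.0), n_permutations=0
            )

    def test_permutation_p_reproducible(self, rng):
        shapes = rng.standard_normal((30, 8))
        sizes = rng.lognormal(0.0, 0.1, size=30)
        r1 = allometry_regression(shapes, sizes, n_permutations=199, seed=3)
        r2 = allometry_regression(shapes, sizes, n_permutations=199, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1.0 / 200.0


class TestDisparity:
    def test_identical_members_zero_variance(self):
        shapes = np.tile(np.arange(6.0), (4, 1))
        res = morphological_disparity(shapes, ["g"] * 4)
        assert res.group_variances["g"] == 0.0

    def test_two_member_group_closed_form(self):
        # two vectors at distance d: each d/2 from the mean, denominator n=2
        a = np.zeros(6)
        b = np.zeros(6)
        b[0] = 0.3
        res = morphological_disparity(np.stack([a, b]), ["g", "g"])
        assert res.group_variances["g"] == pytest.approx(0.3**2 / 4, abs=1e-15)

    def test_matches_isotropic_noise_expectation(self):
        # superimposition absorbs 4 of the 2k dof: PV ~ (2k-4) sigma^2
        sigma = 0.005
        spec = SyntheticSpec(
            group_sizes={(Species.JAPONICUS, Sex.FEMALE): 500},
            species_effect_d=0.0,
            sex_effect_d=0.0,
            allometry_slope=0.0,
            individual_noise=sigma,
            n_replicate_specimens=0,
            seed=21,
        )
        res = gpa(generate_study(spec))
        disp = morphological_disparity(
            res.shape_vectors(), ["japonicus"] * 500
        )
        expected = 32 * sigma**2
        assert disp.group_variances["japonicus"] == pytest.approx(expected, rel=0.10)

    def test_invariant_under_common_rotation(self, rng):
        shapes = rng.standard_normal((20, 36)) * 0.01
        theta = 0.83
        c, s = np.cos(theta), np.sin(theta)
        rot = np.kron(np.eye(18), np.array([[c, -s], [s, c]]))
        groups = np.repeat(["a", "b"], 10)
        r1 = morphological_disparity(shapes, groups)
        r2 = morphological_disparity(shapes @ rot.T, groups)
        for g in ("a", "b"):
            assert r1.group_variances[g] == pytest.approx(
                r2.group_variances[g], rel=1e-9
            )

    def test_pairwise_difference_and_permutation_p(self, rng):
        shapes = np.concatenate(
            [rng.standard_normal((30, 8)) * 0.001, rng.standard_normal((30, 8)) * 0.05]
        )
        groups = np.repeat(["quiet", "loud"], 30)
        res = morphological_disparity(shapes, groups, n_permutations=199, seed=1)
        pair = ("loud", "quiet")
        assert res.pairwise_abs_differences[pair] > 0
        assert res.pairwise_p[pair] == pytest.approx(1 / 200, abs=1e-12)


class TestObserverAnalyses:
    def test_identical_measurements_zero_f(self):
        sizes = np.tile([10.0, 11.0, 12.0], 3)
        observers = np.repeat(["o1", "o2", "o3"], 3)
        specimens = np.tile(["w1", "w2", "w3"], 3)
        res = observer_size_effect(sizes, observers, specimens, n_permutations=0)
        assert res.statistic_F == 0.0

    def test_f_matches_three_group_oracle(self, rng):
        sizes = rng.lognormal(7.0, 0.05, size=30)
        observers = np.repeat(["o1", "o2", "o3"], 10)
        res = observer_size_effect(sizes, observers, n_permutations=0)
        oracle = f_oneway(sizes[:10], sizes[10:20], sizes[20:])
        assert res.statistic_F == pytest.approx(oracle.statistic, abs=1e-10)

    def test_uncrossed_design_rejected(self):
        sizes = np.arange(1.0, 5.0)
        observers = ["o1", "o1", "o2", "o2"]
        specimens = ["w1", "w2", "w3", "w4"]
        with pytest.raises(ValueError, match="not measured by every observer"):
            observer_size_effect(sizes, observers, specimens, n_permutations=0)

    def test_identical_replicates_zero_within_specimen_pv(self):
        v = np.arange(8.0)
        shapes = np.stack([v, v, v, v + 1, v + 1, v + 1])
        res = observer_repeatability(
            shapes,
            specimens=["w1"] * 3 + ["w2"] * 3,
            observers=["o1", "o2", "o3"] * 2,
            species=["japonicus"] * 6,
        )
        assert res.within_specimen_pv == 0.0

    def test_invariant_to_replicate_relabeling(self, rng):
        shapes = rng.standard_normal((12, 8))
        specimens = np.repeat([f"w{i}" for i in range(4)], 3)
        observers = np.tile(["o1", "o2", "o3"], 4)
        shuffled = np.tile(["o3", "o1", "o2"], 4)
        r1 = observer_repeatability(shapes, specimens, observers, ["japonicus"] * 12)
        r2 = observer_repeatability(shapes, specimens, shuffled, ["japonicus"] * 12)
        assert r1.within_specimen_pv == pytest.approx(r2.within_specimen_pv, abs=1e-15)

    def test_unreplicated_specimen_excluded_with_warning(self, rng):
        shapes = rng.standard_normal((7, 8))
        specimens = ["w1"] * 3 + ["w2"] * 3 + ["w3"]
        observers = ["o1", "o2", "o3"] * 2 + ["o1"]
        with pytest.warns(RuntimeWarning, match="no replicate"):
            res = observer_repeatability(
                shapes, specimens, observers, ["japonicus"] * 7
            )
        assert res.n_specimens == 2 and res.n_excluded == 1

    def test_observer_noise_ratio_recovered(self):
        # sigma_obs = sigma_ind / 2: within-specimen PV over 3 replicates has
        # expectation (2/3)(2k-4) sigma_obs^2, biological PV ~ (2k-4) sigma_ind^2,
        # so the ratio recovers ~(2/3)/4 at 40 specimens x 3 replicates
        sigma_ind = 0.008
        spec = SyntheticSpec(
            group_sizes={(Species.JAPONICUS, Sex.FEMALE): 40},
            species_effect_d=0.0,
            sex_effect_d=0.0,
            allometry_slope=0.0,
            individual_noise=sigma_ind,
            observer_noise=sigma_ind / 2,
            n_replicate_specimens=40,
            seed=33,
        )
        ds = generate_study(spec)
        meta = ds.metadata_frame()
        rep = ds.subset((meta["replicate"] == 2).to_numpy())
        rep_meta = meta[meta["replicate"] == 2]
        res = gpa(rep)
        rr = observer_repeatability(
            res.shape_vectors(),
            rep_meta["id"].to_numpy(),
            rep_meta["observer"].to_numpy(),
            rep_meta["species"].to_numpy(),
        )
        expected_within = (2 / 3) * 32 * (sigma_ind / 2) ** 2
        assert rr.within_specimen_pv == pytest.approx(expected_within, rel=0.20)
        # within-species reference here includes one observer-jittered copy
        expected_species = (39 / 40) * 32 * (sigma_ind**2 + (sigma_ind / 2) ** 2)
        expected_ratio = expected_within / expected_species
        assert rr.ratio == pytest.approx(expected_ratio, rel=0.20)
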