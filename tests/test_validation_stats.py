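"""Validation statistics: oracles by enumeration/simulation and selection rules."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from swaybalance import (
    CohortSpec,
    CorrelationResult,
    assess_normality,
    fit_linear_regression_enter,
    generate_cohort,
    log_transform_if_needed,
    mann_whitney_u,
    pearson_correlation,
    run_validation,
    select_predictors,
)
from swaybalance.pipeline import cop_parameter_table, truth_parameter_table
from swaybalance.stats import correlation_strength_label, effect_size_label


class TestAssessNormality:
    def test_normal_sample_usually_passes(self):
        hits = sum(
            assess_normality(
                np.random.default_rng(s).standard_normal(50)
            ).verdict == "normal"
            for s in range(100)
        )
        assert hits >= 90  # Shapiro-Wilk level at alpha = 0.05

    def test_lognormal_sample_usually_fails(self):
        hits = sum(
            assess_normality(
                np.exp(np.random.default_rng(s).standard_normal(50))
            ).verdict == "non_normal"
            for s in range(100)
        )
        assert hits >= 95  # test power against sigma=1 log-normal

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="3"):
            assess_normality([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            assess_normality([4.0, 4.0, 4.0, 4.0])


class TestLogTransform:
    def test_normal_verdict_is_noop(self, rng):
        x = rng.standard_normal(30)
        rep = assess_normality(x)
        out, flag = log_transform_if_needed(x, rep)
        if rep.verdict == "normal":
            np.testing.assert_array_equal(out, x)
            assert flag is False

    def test_exact_logs(self):
        x = np.array([1.0, np.e, np.e**2])
        rep = assess_normality(np.exp(np.random.default_rng(0).standard_normal(50)))
        assert rep.verdict == "non_normal"
        out, flag = log_transform_if_needed(x, rep)
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0], atol=1e-12)
        assert flag is True

    def test_zero_values_offset_by_smallest_positive(self):
        rep = assess_normality(np.exp(np.random.default_rng(0).standard_normal(50)))
        x = np.array([0.0, 0.5, 2.0])
        out, _ = log_transform_if_needed(x, rep)
        np.testing.assert_allclose(out, np.log(x + 0.5), atol=1e-12)

    def test_all_nonpositive_rejected(self):
        rep = assess_normality(np.exp(np.random.default_rng(0).standard_normal(50)))
        with pytest.raises(ValueError, match="nonpositive"):
            log_transform_if_needed(np.array([-1.0, -2.0, 0.0]), rep)


class TestPearsonCorrelation:
    def test_perfect_linear_relation(self, rng):
        x = rng.standard_normal(20)
        assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.strength_label == "strong"

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("r,label", [
        (0.1, "very weak"), (-0.3, "weak"), (0.5, "moderate"),
        (0.7, "strong"), (-0.95, "very strong"),
    ])
    def test_strength_bands(self, r, label):
        assert correlation_strength_label(r) == label


class TestMannWhitneyU:
    def test_extreme_separation_enumeration(self):
        # all 20 arrangements of ranks: only 2 as extreme -> p = 0.1
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups_midrank_u(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u_statistic == 8.0  # n1*n2/2 by symmetry

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_full_enumeration_oracle(self, rng):
        # independent oracle: enumerate all C(n1+n2, n1) group assignments
        # and count arrangements with |U - n1 n2/2| at least as extreme
        for _ in range(25):
            n1 = int(rng.integers(2, 9))
            n2 = int(rng.integers(2, 9))
            vals = rng.permutation(np.arange(n1 + n2, dtype=float))
            a, b = vals[:n1], vals[n1:]
            res = mann_whitney_u(a, b)
            assert res.method == "exact"

            pooled = np.concatenate([a, b])
            idx = set(range(n1 + n2))
            u_obs = sum(x > y for x in a for y in b)
            mu = n1 * n2 / 2
            count = total = 0
            for comb in combinations(range(n1 + n2), n1):
                aa = pooled[list(comb)]
                bb = pooled[list(idx - set(comb))]
                u = sum(x > y for x in aa for y in bb)
                count += abs(u - mu) >= abs(u_obs - mu)
                total += 1
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_type_one_error_rate_at_nominal_level(self):
        # two n=30 samples from one distribution: rejection rate near 0.05
        rng = np.random.default_rng(321)
        rejections = sum(
            mann_whitney_u(rng.standard_normal(30),
                           rng.standard_normal(30)).p_value < 0.05
            for _ in range(1000)
        )
        assert 30 <= rejections <= 70


class TestSelectPredictors:
    @staticmethod
    def corr(r, p=0.01, n=40):
        return CorrelationResult(r=r, p_value=p, n=n,
                                 strength_label=correlation_strength_label(r))

    def test_r_threshold_gate(self):
        cors = {"Vmean_COMx": self.corr(0.30), "Vmean_COMy": self.corr(0.20)}
        inter = pd.DataFrame(np.eye(2), index=list(cors), columns=list(cors))
        assert select_predictors(cors, inter) == ["Vmean_COMx"]

    def test_significance_gate(self):
        cors = {"Vmean_COMx": self.corr(0.40, p=0.20)}
        inter = pd.DataFrame([[1.0]], index=list(cors), columns=list(cors))
        assert select_predictors(cors, inter) == []

    def test_collinear_pair_drops_weaker(self):
        cors = {"Vmean_COMx": self.corr(0.6), "Vmean_COMy": self.corr(0.5)}
        inter = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]],
                             index=list(cors), columns=list(cors))
        assert select_predictors(cors, inter) == ["Vmean_COMx"]

    def test_collinear_tie_drops_later_column(self):
        cors = {"Vmean_COMx": self.corr(0.5), "Ctotal_COMy": self.corr(0.5)}
        inter = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                             index=list(cors), columns=list(cors))
        # equal |r|: the later name in the canonical parameter order goes
        assert select_predictors(cors, inter) == ["Vmean_COMx"]


class TestEnterRegression:
    def test_r_squared_equals_r_squared_identity(self, rng):
        x = rng.standard_normal(60)
        y = 0.8 * x + rng.standard_normal(60)
        r = pearson_correlation(x, y).r
        model = fit_linear_regression_enter(
            y, pd.DataFrame({"x": x}), outcome_name="y"
        )
        assert model.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_perfect_fit(self, rng):
        x = rng.standard_normal(30)
        model = fit_linear_regression_enter(x, pd.DataFrame({"x": x}))
        assert model.r_squared == pytest.approx(1.0)
        assert model.effect_size_label == "large"

    def test_population_r_squared_recovery(self, rng):
        # y = 0.5 x1 + 0.3 x2 + e with var(e) chosen for population R2 = 0.6:
        # var(signal) = 0.25 + 0.09 = 0.34 -> var(e) = 0.34 * 0.4/0.6
        n = 500
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        sigma = np.sqrt(0.34 * 0.4 / 0.6)
        y = 0.5 * x1 + 0.3 * x2 + rng.normal(0, sigma, n)
        model = fit_linear_regression_enter(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert model.r_squared == pytest.approx(0.6, abs=0.05)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            fit_linear_regression_enter(rng.standard_normal(30), X)

    @pytest.mark.parametrize("r2,label", [
        (0.01, "negligible"), (0.05, "small"), (0.2, "medium"), (0.3, "large"),
    ])
    def test_cohen_bands(self, r2, label):
        assert effect_size_label(r2) == label


def make_tables(coupling_noise_sd=0.0, seed=0, n=15):
    """Trial tables from ground-truth trajectories and simulated COP."""
    spec = CohortSpec(n_cp=n, n_control=n, coupling_noise_sd=coupling_noise_sd,
                      seed=seed)
    trials = generate_cohort(spec, render_video=False)
    img = truth_parameter_table(trials)
    cop = cop_parameter_table(trials)
    return img, cop


class TestRunValidation:
    def test_noise_free_coupling_gives_high_correlation(self):
        img, cop = make_tables(coupling_noise_sd=0.0, seed=4)
        report = run_validation(img, cop)
        vr = report.correlations.query(
            "image_parameter == 'Vmean_COMr' and cop_parameter == 'Vmean_COPr'"
        )
        assert len(vr) == 4
        assert (vr["r"] >= 0.95).all()

    def test_group_difference_detected(self):
        img, cop = make_tables(seed=6, n=20)
        report = run_validation(img, cop)
        vr = report.group_tests.query("parameter == 'Vmean_COMr'")
        assert (vr["p_value"] < 0.05).all()

    def test_shuffled_pairing_destroys_correlation(self, rng):
        img, cop = make_tables(coupling_noise_sd=0.0, seed=8, n=20)
        # permute the COP values across all subjects within each condition,
        # breaking the image/COP pairing entirely (groups included)
        cop_shuffled = cop.copy()
        cols = [c for c in cop.columns if c.startswith(("Vmean", "Vstd", "Ctotal"))]
        for _, idx in cop_shuffled.groupby("condition").groups.items():
            perm = rng.permutation(len(idx))
            block = cop_shuffled.loc[idx, cols].to_numpy()
            cop_shuffled.loc[idx, cols] = block[perm]
        report = run_validation(img, cop_shuffled)
        # null E|r| ~ 0.8/sqrt(n) ~ 0.13 at n = 40
        assert report.correlations["r"].abs().mean() < 0.15

    def test_key_mismatch_reported(self):
        img, cop = make_tables(n=3)
        cop = cop[cop["subject_id"] != "cp000"]
        with pytest.raises(ValueError, match="cp000"):
            run_validation(img, cop)

    def test_selection_respects_thresholds(self):
        img, cop = make_tables(coupling_noise_sd=0.5, seed=10, n=15)
        report = run_validation(img, cop)
        corr = report.correlations.set_index(
            ["condition", "image_parameter", "cop_parameter"])
        for _, row in report.models.iterrows():
            for pred in row["predictors"].split("+"):
                cr = corr.loc[(row["condition"], pred, row["outcome"])]
                assert abs(cr["r"]) > 0.25
                assert cr["p_value"] < 0.05

    def test_correlation_monotone_in_coupling_noise(self):
        # median image-COP r never increases as COP decoupling noise rises
        noise_levels = [0.0, 1.0, 3.0, 8.0]
        medians = []
        for noise in noise_levels:
            rs = []
            for rep in range(5):
                img, cop = make_tables(coupling_noise_sd=noise,
                                       seed=100 + rep, n=8)
                report = run_validation(img, cop)
                sub = report.correlations.query(
                    "image_parameter == 'Vmean_COMr' "
                    "and cop_parameter == 'Vmean_COPr'")
                rs.extend(sub["r"].tolist())
            medians.append(np.median(rs))
        assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))
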