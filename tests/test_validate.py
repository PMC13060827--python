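"""Batch-removal and preservation metrics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gamharm import validate as vd
from gamharm.validate import (
    MetricError,
    cohort_r2_increment,
    mean_pairwise_ks,
    moment_differences,
    retention_report,
    sex_effect,
    spearman_age,
)


def _frame(cohort, age, sex, y, name="f"):
    return pd.DataFrame({"cohort": cohort, "age": age, "sex": sex, name: y})


class TestCohortR2Increment:
    def test_null_simulation_is_near_zero(self):
        rng = np.random.default_rng(10)
        n = 3000
        age = rng.uniform(20, 80, n)
        sex = rng.integers(1, 3, n)
        cohort = rng.choice(["A", "B", "C"], n)
        y = 2.0 + 0.05 * age + 0.3 * (sex == 2) + rng.normal(0, 1, n)
        df = _frame(cohort, age, sex, y)
        assert cohort_r2_increment(df, "f") < 0.005

    def test_matches_anova_sum_of_squares_oracle(self):
        """Pure cohort shifts with no covariate effect: the increment equals
        the between-cohort share of the total sum of squares."""
        rng = np.random.default_rng(11)
        n = 1500
        age = rng.uniform(20, 80, n)
        sex = rng.integers(1, 3, n)
        cohort = rng.choice(["A", "B", "C"], n)
        shift = {"A": -1.0, "B": 0.0, "C": 1.5}
        y = np.array([shift[c] for c in cohort]) + rng.normal(0, 1, n)
        df = _frame(cohort, age, sex, y)
        inc = cohort_r2_increment(df, "f")
        # oracle: ANOVA decomposition after residualising on the baseline
        Xb = np.column_stack([np.ones(n), age - age.mean(),
                              (age - age.mean()) ** 2, (age - age.mean()) ** 3,
                              (sex != 1).astype(float)])
        resid = y - Xb @ np.linalg.lstsq(Xb, y, rcond=None)[0]
        sst = np.sum((y - y.mean()) ** 2)
        groups = pd.Series(resid).groupby(pd.Series(cohort))
        ssb = sum(len(g) * g.mean() ** 2 for _, g in groups)
        assert inc == pytest.approx(ssb / sst, abs=0.005)

    def test_single_cohort_is_an_error(self):
        df = _frame("A", np.linspace(20, 80, 50), 1, np.random.default_rng(0).normal(size=50))
        with pytest.raises(MetricError):
            cohort_r2_increment(df, "f")

    def test_increment_nonnegative_and_zero_under_duplicate_labels(self):
        rng = np.random.default_rng(3)
        n = 400
        df = _frame(rng.choice(["A", "B"], n), rng.uniform(20, 80, n),
                    rng.integers(1, 3, n), rng.normal(size=n))
        assert cohort_r2_increment(df, "f") >= 0.0


class TestMeanPairwiseKS:
    def test_identical_residuals_give_zero(self):
        rng = np.random.default_rng(1)
        n = 300
        age = rng.uniform(20, 80, n)
        sex = rng.integers(1, 3, n)
        y = rng.normal(size=n)
        df = pd.concat([_frame("A", age, sex, y), _frame("B", age, sex, y)],
                       ignore_index=True)
        assert mean_pairwise_ks(df, "f") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        # no covariate signal: residualisation leaves the separation intact
        df = pd.concat([
            _frame("A", [30.0, 40, 50, 60], [1, 2, 1, 2], [1.0, 2, 3, 2]),
            _frame("B", [30.0, 40, 50, 60], [1, 2, 1, 2], [101.0, 102, 103, 102]),
        ], ignore_index=True)
        assert mean_pairwise_ks(df, "f") == 1.0

    def test_homogeneous_split_below_null_quantile(self):
        rng = np.random.default_rng(8)
        n = 1000
        age = rng.uniform(20, 80, 2 * n)
        sex = rng.integers(1, 3, 2 * n)
        y = 0.02 * age + rng.normal(size=2 * n)
        cohort = np.array(["A"] * n + ["B"] * n)
        df = _frame(cohort, age, sex, y)
        assert mean_pairwise_ks(df, "f") < 1.36 * np.sqrt(2.0 / n)

    def test_mean_over_all_pairs(self):
        rng = np.random.default_rng(9)
        n = 400
        frames = [_frame(lab, rng.uniform(20, 80, n), rng.integers(1, 3, n),
                         rng.normal(loc, 1, n))
                  for lab, loc in (("A", 0.0), ("B", 0.0), ("C", 3.0))]
        df = pd.concat(frames, ignore_index=True)
        val = mean_pairwise_ks(df, "f")
        assert 0.2 < val < 0.8  # two separated pairs out of three


class TestMomentDifferences:
    def test_identical_samples_are_zero(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=200)
        df = pd.concat([_frame("A", 50.0, 1, y), _frame("B", 50.0, 1, y)],
                       ignore_index=True)
        assert moment_differences(df, "f", ("A", "B")) == (0.0, 0.0, 0.0)

    def test_scaling_moves_only_log_sd_ratio(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=500)
        df = pd.concat([_frame("A", 50.0, 1, y), _frame("B", 50.0, 1, 2.0 * y)],
                       ignore_index=True)
        lsd, dskew, dkurt = moment_differences(df, "f", ("A", "B"))
        assert lsd == pytest.approx(np.log(2.0), abs=1e-12)
        assert dskew == pytest.approx(0.0, abs=1e-12)
        assert dkurt == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_log_sd_ratio(self):
        rng = np.random.default_rng(4)
        ya, yb = rng.normal(0, 1, 400), rng.normal(0, 1.7, 400)
        df1 = pd.concat([_frame("A", 50.0, 1, ya), _frame("B", 50.0, 1, yb)],
                        ignore_index=True)
        df2 = df1.copy()
        df2["f"] = df2["f"] * 1000.0  # change of units
        assert moment_differences(df1, "f", ("A", "B"))[0] == pytest.approx(
            moment_differences(df2, "f", ("A", "B"))[0], rel=1e-12)

    def test_known_population_moments(self):
        rng = np.random.default_rng(5)
        n = 10000
        ya = rng.normal(0, 1, n)                      # skew 0, excess kurt 0
        yb = rng.exponential(1.0, n)                  # skew 2, excess kurt 6
        df = pd.concat([_frame("A", 50.0, 1, ya), _frame("B", 50.0, 1, yb)],
                       ignore_index=True)
        _, dskew, dkurt = moment_differences(df, "f", ("A", "B"))
        assert dskew == pytest.approx(2.0, abs=0.3)
        assert dkurt == pytest.approx(6.0, abs=1.5)

    def test_zero_sd_is_an_error(self):
        df = pd.concat([_frame("A", 50.0, 1, np.ones(10)),
                        _frame("B", 50.0, 1, np.arange(10.0))], ignore_index=True)
        with pytest.raises(MetricError):
            moment_differences(df, "f", ("A", "B"))


class TestSpearmanAge:
    def test_perfect_and_monotone_invariant(self):
        rng = np.random.default_rng(6)
        age = rng.uniform(20, 80, 200)
        df = pd.DataFrame({"cohort": "A", "age": age, "sex": 1,
                           "lin": age, "expo": np.exp(age / 20.0)})
        out = spearman_age(df, ["lin", "expo"]).set_index("feature")
        assert out.loc["lin", "spearman_rho"] == pytest.approx(1.0)
        assert out.loc["expo", "spearman_rho"] == pytest.approx(1.0)

    def test_known_population_rho(self):
        # bivariate normal with Pearson r chosen so Spearman rho = 0.5
        rho_s = 0.5
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        rng = np.random.default_rng(13)
        n = 4000
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r ** 2) * rng.normal(size=n)
        df = pd.DataFrame({"cohort": "A", "age": 50 + 10 * x, "sex": 1, "f": y})
        est = spearman_age(df, ["f"])["spearman_rho"].iloc[0]
        assert est == pytest.approx(rho_s, abs=3.0 / np.sqrt(n))

    def test_constant_feature_is_an_error(self):
        df = pd.DataFrame({"cohort": "A", "age": np.linspace(20, 80, 30),
                           "sex": 1, "f": 1.0})
        with pytest.raises(MetricError):
            spearman_age(df, ["f"])


class TestSexEffect:
    def test_hand_computed_pooled_d(self):
        df = pd.DataFrame({"cohort": "A", "age": np.arange(6.0),
                           "sex": [1, 1, 1, 2, 2, 2],
                           "f": [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]})
        out = sex_effect(df, ["f"])
        assert out["cohens_d"].iloc[0] == pytest.approx(-2.0, abs=1e-12)

    def test_identical_groups(self):
        df = pd.DataFrame({"cohort": "A", "age": np.arange(6.0),
                           "sex": [1, 1, 1, 2, 2, 2],
                           "f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = sex_effect(df, ["f"])
        assert out["cohens_d"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_affine_invariance_of_d(self):
        rng = np.random.default_rng(14)
        n = 300
        df = pd.DataFrame({"cohort": "A", "age": rng.uniform(20, 80, n),
                           "sex": rng.integers(1, 3, n)})
        df["f"] = 1.0 + 0.8 * (df["sex"] == 2) + rng.normal(0, 1, n)
        d1 = sex_effect(df, ["f"])["cohens_d"].iloc[0]
        df["f"] = 100.0 + 42.0 * df["f"]
        d2 = sex_effect(df, ["f"])["cohens_d"].iloc[0]
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_fdr_recovers_planted_effects(self):
        """5 real effects (d=0.8) among 50 features at n=200: BH at q<0.05
        recovers most and keeps false positives rare."""
        rng = np.random.default_rng(15)
        n, m, m_true = 200, 50, 5
        sex = rng.integers(1, 3, n)
        df = pd.DataFrame({"cohort": "A", "age": rng.uniform(20, 80, n), "sex": sex})
        feats = []
        for j in range(m):
            eff = 0.8 if j < m_true else 0.0
            df[f"g{j}"] = eff * (sex == 2) + rng.normal(0, 1, n)
            feats.append(f"g{j}")
        out = sex_effect(df, feats).set_index("feature")
        hits = out[out["q"] < 0.05].index
        true_hits = sum(1 for h in hits if int(h[1:]) < m_true)
        false_hits = len(hits) - true_hits
        assert true_hits >= 4
        assert false_hits <= 2

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(16)
        n = 80
        sex = rng.integers(1, 3, n)
        df = pd.DataFrame({"cohort": "A", "age": rng.uniform(20, 80, n), "sex": sex})
        feats = []
        for j in range(12):
            df[f"g{j}"] = 0.1 * j * (sex == 2) + rng.normal(0, 1, n)
            feats.append(f"g{j}")
        out = sex_effect(df, feats).sort_values("p")
        assert np.all(np.diff(out["q"].to_numpy()) >= -1e-12)


class TestRetention:
    def test_no_flags_no_loss(self):
        rng = np.random.default_rng(17)
        pre = pd.DataFrame({"f": rng.normal(size=100)})
        out = retention_report(pre, pre.copy(), ["f"])
        assert out["lost"].iloc[0] == 0
        assert out["loss_rate"].iloc[0] == 0.0

    def test_counts_and_rates(self):
        pre = pd.DataFrame({"f": np.arange(1000.0)})
        post = pre.copy()
        post.loc[[3, 500, 999], "f"] = np.nan
        out = retention_report(pre, post, ["f"])
        assert out["lost"].iloc[0] == 3
        assert out["loss_rate"].iloc[0] == pytest.approx(0.003)
        assert out.attrs["overall"]["lost"] == 3

    def test_invalid_pre_does_not_count_as_lost(self):
        pre = pd.DataFrame({"f": [1.0, np.nan, 3.0]})
        post = pd.DataFrame({"f": [1.0, np.nan, np.nan]})
        out = retention_report(pre, post, ["f"])
        assert out["lost"].iloc[0] == 1
        assert out["valid_pre"].iloc[0] == 2

    def test_misaligned_tables_error(self):
        with pytest.raises(MetricError):
            retention_report(pd.DataFrame({"f": [1.0]}),
                             pd.DataFrame({"f": [1.0, 2.0]}), ["f"])
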