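import numpy as np
import pandas as pd
import pytest
from scipy import stats

from octarcd.cohort_stats import (
    ContingencyTable,
    SubgroupRule,
    SummaryStats,
    anova_from_summary,
    chi_square,
    dichotomize,
    multiple_regression,
    one_way_anova,
    pooled_t_from_summary,
    significance_flag,
    subgroup_analysis,
)

# Published three-group contingency tables (counts per group row).
EYE = [[47, 39], [52, 38], [21, 15]]
SEX = [[31, 55], [46, 44], [16, 20]]
SMOKE = [[75, 15], [25, 11]]
ALCOHOL = [[74, 16], [28, 8]]
INSULIN = [[74, 16], [24, 12]]


def _sample_with_summary(mean, sd, n, rng):
    """Exact-mean/SD sample via z-scoring a random draw."""
    x = rng.normal(size=n)
    z = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * z


class TestChiSquare:
    def test_eye_laterality_table(self):
        r = chi_square(EYE)
        assert r.p_value == pytest.approx(0.892, abs=5e-4)
        assert r.statistic == pytest.approx(0.229, abs=0.002)
        assert r.df == 2

    def test_perfect_homogeneity(self):
        r = chi_square([[10, 10], [10, 10]])
        assert r.statistic == 0
        assert r.p_value == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero row or column"):
            chi_square([[0, 0], [5, 5]])

    def test_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(((1,),))
        with pytest.raises(ValueError):
            ContingencyTable(((1, -2), (3, 4)))

    @pytest.mark.parametrize(
        "table", [[[10, 5], [7, 8]], [[4, 11], [9, 6]], [[12, 3], [8, 7]]]
    )
    def test_against_monte_carlo_multinomial_null(self, table):
        obs = np.asarray(table)
        n = obs.sum()
        probs = np.outer(obs.sum(1), obs.sum(0)).astype(float) / n**2
        r = np.random.default_rng(99)
        sims = r.multinomial(n, probs.ravel(), size=100_000).reshape(-1, 2, 2)
        rows, cols = sims.sum(2), sims.sum(1)
        ok = (rows > 0).all(1) & (cols > 0).all(1)
        sims, rows, cols = sims[ok], rows[ok], cols[ok]
        expected = rows[:, :, None] * cols[:, None, :] / n
        sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        mc_p = (sim_stats >= chi_square(table).statistic - 1e-9).mean()
        assert chi_square(table).p_value == pytest.approx(mc_p, abs=0.02)


class TestPooledT:
    def test_duration_comparison(self):
        r = pooled_t_from_summary(
            SummaryStats(5.47, 5.34, 90), SummaryStats(7.02, 5.65, 36)
        )
        assert r.p_value == pytest.approx(0.150, abs=5e-4)
        assert abs(r.statistic) == pytest.approx(1.448, abs=0.002)
        assert r.df == 124

    def test_identical_summaries(self):
        s = SummaryStats(5.0, 1.0, 20)
        r = pooled_t_from_summary(s, s)
        assert r.statistic == 0
        assert r.p_value == 1

    def test_matches_raw_data_ttest(self, rng):
        a = _sample_with_summary(12.0, 3.0, 40, rng)
        b = _sample_with_summary(10.5, 2.5, 25, rng)
        r = pooled_t_from_summary(
            SummaryStats(a.mean(), a.std(ddof=1), len(a)),
            SummaryStats(b.mean(), b.std(ddof=1), len(b)),
        )
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        assert r.statistic == pytest.approx(t_raw, abs=1e-10)
        assert r.p_value == pytest.approx(p_raw, abs=1e-10)

    def test_degenerate_zero_sds(self):
        assert pooled_t_from_summary(
            SummaryStats(5, 0, 5), SummaryStats(5, 0, 5)
        ).p_value == 1
        assert pooled_t_from_summary(
            SummaryStats(5, 0, 5), SummaryStats(6, 0, 5)
        ).p_value == 0

    def test_welch_flag(self):
        r = pooled_t_from_summary(
            SummaryStats(5.0, 1.0, 10), SummaryStats(6.0, 4.0, 40), welch=True
        )
        assert r.test_name == "welch_t"
        assert r.df < 48  # Welch df smaller than pooled


class TestOneWayAnova:
    def test_identical_groups(self):
        r = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert r.statistic == 0
        assert r.p_value == 1

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=n) for n in (10, 14, 8)]
        r = one_way_anova(groups)
        f, p = stats.f_oneway(*groups)
        assert r.statistic == pytest.approx(f, rel=1e-12)
        assert r.p_value == pytest.approx(p, rel=1e-12)

    def test_against_permutation_oracle(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0.4 * i, 1.0, 8) for i in range(3)]
        r = one_way_anova(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            if one_way_anova(parts).statistic >= r.statistic - 1e-12:
                count += 1
        assert r.p_value == pytest.approx(count / n_perm, abs=0.01)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3]])


class TestAnovaFromSummary:
    def test_matches_raw_anova(self, rng):
        groups = [
            _sample_with_summary(m, s, n, rng)
            for m, s, n in ((43.9, 1.8, 86), (42.4, 3.0, 90), (41.0, 2.7, 36))
        ]
        summaries = [
            SummaryStats(g.mean(), g.std(ddof=1), len(g)) for g in groups
        ]
        raw = one_way_anova(groups)
        summ = anova_from_summary(summaries)
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-10)

    def test_two_groups_f_equals_t_squared(self):
        a, b = SummaryStats(5.47, 5.34, 90), SummaryStats(7.02, 5.65, 36)
        f = anova_from_summary([a, b])
        t = pooled_t_from_summary(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_equal_means_give_zero_f(self):
        r = anova_from_summary(
            [SummaryStats(5, 1, 10), SummaryStats(5, 2, 12), SummaryStats(5, 3, 9)]
        )
        assert r.statistic == 0


def _printed_counts_cohort():
    """Diabetic rows realizing the printed subgroup counts.

    age: 53 NDR + 12 MDR below 55, 37 NDR + 24 MDR above;
    bun: 66 NDR + 27 MDR below 8.2, 3 NDR + 2 MDR above, rest missing;
    ldl_c: 58 NDR + 23 MDR below 3.1, 17 NDR + 8 MDR above, rest missing.
    """
    rows = []

    def add(group, n, **vals):
        for _ in range(n):
            rows.append({"group": group, **vals})

    add("NDR", 53, age=50.0)
    add("NDR", 37, age=60.0)
    add("MDR", 12, age=50.0)
    add("MDR", 24, age=60.0)
    df = pd.DataFrame(rows)
    bun = np.full(len(df), np.nan)
    ndr = np.flatnonzero(df["group"] == "NDR")
    mdr = np.flatnonzero(df["group"] == "MDR")
    bun[ndr[:66]] = 6.0
    bun[ndr[66:69]] = 9.0
    bun[mdr[:27]] = 6.0
    bun[mdr[27:29]] = 9.0
    df["bun"] = bun
    ldl = np.full(len(df), np.nan)
    ldl[ndr[:58]] = 2.5
    ldl[ndr[58:75]] = 3.5
    ldl[mdr[:23]] = 2.5
    ldl[mdr[23:31]] = 3.5
    df["ldl_c"] = ldl
    return df


class TestDichotomize:
    def test_age_55_composition(self):
        d = dichotomize(_printed_counts_cohort(), SubgroupRule("age", 55.0))
        low = d.composition["age < 55.0"]
        assert (low["ndr_pct"], low["mdr_pct"]) == (81.5, 18.5)
        assert (low["ndr_n"], low["mdr_n"]) == (53, 12)

    def test_bun_composition_with_missing(self):
        d = dichotomize(_printed_counts_cohort(), SubgroupRule("bun", 8.2))
        low = d.composition["bun < 8.2"]
        assert (low["ndr_pct"], low["mdr_pct"]) == (71.0, 29.0)
        assert d.n_missing == 126 - 66 - 27 - 3 - 2
        assert len(d.low) + len(d.high) == 126 - d.n_missing

    def test_empty_arm_flagged(self):
        df = _printed_counts_cohort()
        d = dichotomize(df, SubgroupRule("age", 200.0))
        assert d.composition["age > 200.0"]["undefined"]
        assert d.composition["age > 200.0"]["ndr_pct"] is None

    def test_ties_go_high(self):
        df = pd.DataFrame(
            {"group": ["NDR", "NDR"], "x": [7.0, 6.9]}
        )
        d = dichotomize(df, SubgroupRule("x", 7.0))
        assert len(d.high) == 1 and len(d.low) == 1

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            dichotomize(_printed_counts_cohort(), SubgroupRule("hdl", 1.0))


def _two_arm_cohort(rng, n_low=65, n_high=61, mean_low=50.7, mean_high=47.1,
                    sd_low=4.6, sd_high=6.8, n_control=86):
    rows = []
    for _ in range(n_control):
        rows.append({"group": "Control", "age": rng.normal(52.5, 9.1),
                     "rcd_srcl": rng.normal(43.9, 1.8),
                     "rcd_drcl": rng.normal(52.6, 3.0)})
    for n, mean, sd, age_mu in ((n_low, mean_low, sd_low, 48.0),
                                (n_high, mean_high, sd_high, 62.0)):
        for _ in range(n):
            rows.append({"group": "NDR", "age": rng.normal(age_mu, 1.0),
                         "rcd_srcl": rng.normal(42.0, 3.0),
                         "rcd_drcl": rng.normal(mean, sd)})
    return pd.DataFrame(rows)


class TestSubgroupAnalysis:
    def test_empty_rule_list(self):
        df = _two_arm_cohort(np.random.default_rng(0))
        report = subgroup_analysis(df, [])
        assert report.empty

    def test_report_shape_and_flags(self):
        df = _two_arm_cohort(np.random.default_rng(1))
        report = subgroup_analysis(df, [SubgroupRule("age", 55.0)])
        assert len(report) == 3  # low arm, high arm, arm-vs-arm
        arm_row = report[report["arm"] == "low vs high"].iloc[0]
        assert 0 <= arm_row["DRCL_p_vs_control"] <= 1

    def test_power_at_published_arm_parameters(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            df = _two_arm_cohort(np.random.default_rng(seed))
            rep = subgroup_analysis(df, [SubgroupRule("age", 55.0)])
            p = rep.loc[rep["arm"] == "low vs high", "DRCL_p_vs_control"].iloc[0]
            if p < 0.05:
                hits += 1
        assert hits >= 0.90 * n_seeds

    def test_null_cohort_type_i_calibrated(self):
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            df = _two_arm_cohort(rng, mean_low=49.0, mean_high=49.0,
                                 sd_low=5.0, sd_high=5.0, n_control=4)
            rep = subgroup_analysis(df, [SubgroupRule("age", 55.0)])
            p = rep.loc[rep["arm"] == "low vs high", "DRCL_p_vs_control"].iloc[0]
            if p < 0.05:
                hits += 1
        assert 0.03 <= hits / n_seeds <= 0.07

    def test_tiny_arm_not_testable(self):
        df = _two_arm_cohort(np.random.default_rng(2), n_high=1)
        rep = subgroup_analysis(df, [SubgroupRule("age", 55.0)])
        high_row = rep[rep["arm"].str.contains(">")].iloc[0]
        assert high_row["DRCL_flag_vs_control"] == "not testable"


class TestMultipleRegression:
    def test_noise_free_exact_fit(self, rng):
        n = 60
        df = pd.DataFrame({
            "age": rng.uniform(40, 70, n),
            "bmi": rng.uniform(20, 28, n),
        })
        df["y"] = 50.0 - 0.1 * df["age"]
        fit = multiple_regression(df, "y", ["age", "bmi"])
        assert fit.params["age"] == pytest.approx(-0.1, abs=1e-10)
        assert fit.params["bmi"] == pytest.approx(0.0, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_duplicated_column_rejected(self, rng):
        n = 30
        df = pd.DataFrame({"age": rng.uniform(40, 70, n)})
        df["age2"] = df["age"]
        df["y"] = rng.normal(size=n)
        with pytest.raises(ValueError, match="age"):
            multiple_regression(df, "y", ["age", "age2"])

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"age": [50.0, 51.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="complete-case"):
            multiple_regression(df, "y", ["age"])

    def test_slope_coverage(self):
        hits = 0
        n_seeds = 300
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            age = rng.normal(53, 11, 126)
            y = 50 - 0.1 * age + rng.normal(0, 5, 126)
            df = pd.DataFrame({"age": age, "y": y})
            fit = multiple_regression(df, "y", ["age"])
            if abs(fit.params["age"] + 0.1) <= 2 * fit.bse["age"]:
                hits += 1
        assert hits >= 0.93 * n_seeds


class TestTypeIError:
    def test_three_tests_calibrated_under_null(self):
        n_sims = 1000
        rng = np.random.default_rng(2024)
        rej = {"chi2": 0, "t": 0, "anova": 0}
        for _ in range(n_sims):
            table = rng.multinomial(200, [0.25] * 4).reshape(2, 2)
            if (table.sum(0) > 0).all() and (table.sum(1) > 0).all():
                if chi_square(table).p_value < 0.05:
                    rej["chi2"] += 1
            a, b = rng.normal(size=30), rng.normal(size=30)
            r = pooled_t_from_summary(
                SummaryStats(a.mean(), a.std(ddof=1), 30),
                SummaryStats(b.mean(), b.std(ddof=1), 30),
            )
            if r.p_value < 0.05:
                rej["t"] += 1
            groups = [rng.normal(size=30) for _ in range(3)]
            if one_way_anova(groups).p_value < 0.05:
                rej["anova"] += 1
        for name, count in rej.items():
            assert 0.03 <= count / n_sims <= 0.07, name


class TestSignificanceFlag:
    @pytest.mark.parametrize(
        "p,flag", [(0.5, ""), (0.04, "a"), (0.005, "b"), (0.0005, "c")]
    )
    def test_thresholds(self, p, flag):
        assert significance_flag(p) == flag
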