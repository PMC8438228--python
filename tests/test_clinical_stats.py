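"""Chi-square tables, rank statistics, Cox fits and cumulative incidence."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rpflux import (
    CohortTable,
    ContingencyTable,
    ContractError,
    DegenerateInputError,
    DomainError,
    agreement,
    build_association_tables,
    chi_square_pvalue,
    cumulative_incidence,
    dichotomize_at_control_mean,
    evaluate_predictions,
    fit_cox_ph,
    mann_whitney_u,
    pearson_chi_square,
    roc_auc,
    spearman_rho,
)
from rpflux.synthetic_cohort import reconstruct_paper_cohort


def make_cohort(**overrides) -> CohortTable:
    n = overrides.pop("n", 6)
    base = {
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": ["male"] * n,
        "age": [60.0] * n,
        "smoking": [False] * n,
        "chemotherapy": [True] * n,
        "pathology": ["SCLC"] * n,
        "stage": ["II"] * n,
        "dose_gy": [50.0] * n,
        "v5": [40.0] * n, "v10": [30.0] * n, "v20": [17.0] * n, "v30": [11.0] * n,
        "rp_grade": [0] * n,
        "time_to_rp_days": [np.nan] * n,
        "followup_days": [90.0] * n,
    }
    base.update(overrides)
    return CohortTable(pd.DataFrame(base))


class TestDichotomize:
    def test_control_mean_threshold_inclusive(self):
        thr, groups = dichotomize_at_control_mean(
            [35.0, 39.34, 37.17], [True, True, False]
        )
        assert thr == 37.17
        assert list(groups) == ["below", "at_or_above", "at_or_above"]

    def test_all_control_constant(self):
        thr, groups = dichotomize_at_control_mean([5.0, 5.0], [True, True])
        assert thr == 5.0
        assert set(groups) == {"at_or_above"}

    def test_empty_control_group(self):
        with pytest.raises(DegenerateInputError):
            dichotomize_at_control_mean([1.0, 2.0], [False, False])


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[22, 19], [2, 5]], 1.505),          # sex vs occurrence
            ([[7, 0], [20, 21]], 6.374),          # smoking vs severe RP
            ([[1, 3], [7, 6], [14, 12], [2, 2], [0, 1]], 2.231),  # age bands
        ],
    )
    def test_published_statistics(self, counts, expected):
        res = pearson_chi_square(ContingencyTable.from_counts(counts))
        assert res.statistic == pytest.approx(expected, abs=5e-4)

    def test_independence_gives_zero(self):
        res = pearson_chi_square(ContingencyTable.from_counts([[10, 10], [10, 10]]))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_and_symmetries(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(int(rng.integers(2, 5)), 2))
            counts[0] += 1  # avoid fully empty tables
            kept = counts[counts.sum(axis=1) > 0]
            if kept.shape[0] < 2 or (kept.sum(axis=0) == 0).any():
                continue
            res = pearson_chi_square(ContingencyTable.from_counts(counts))
            stat, p, df, _ = sps.chi2_contingency(kept, correction=False)
            assert res.statistic == pytest.approx(stat)
            assert res.p_value == pytest.approx(p)
            assert res.df == df
            # invariance: row/column permutation and transposition
            perm = kept[np.argsort(rng.random(kept.shape[0]))][:, ::-1]
            assert pearson_chi_square(
                ContingencyTable.from_counts(perm)
            ).statistic == pytest.approx(res.statistic)
            assert pearson_chi_square(
                ContingencyTable.from_counts(kept.T)
            ).statistic == pytest.approx(res.statistic)

    def test_zero_column_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi_square(ContingencyTable.from_counts([[3, 0], [5, 0]]))

    def test_pvalue_pairs(self):
        assert chi_square_pvalue(0.0, 1) == 1.0
        assert chi_square_pvalue(0.0, 5) == 1.0
        assert chi_square_pvalue(9.397, 3) == pytest.approx(0.024, abs=5e-4)
        assert chi_square_pvalue(2.231, 4) == pytest.approx(0.693, abs=5e-4)

    def test_pvalue_strictly_decreasing_in_statistic(self):
        grid = np.linspace(0, 30, 61)
        for df in (1, 3, 8):
            p = [chi_square_pvalue(x, df) for x in grid]
            assert all(a > b for a, b in zip(p, p[1:]))

    def test_pvalue_domain(self):
        with pytest.raises(DomainError):
            chi_square_pvalue(1.0, 0)
        with pytest.raises(DomainError):
            chi_square_pvalue(-0.5, 1)


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        u, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3], mode="exact")
        assert p == 1.0

    def test_brute_force_pair_counts(self):
        u, _ = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert u == 4.0
        u, _ = mann_whitney_u([1, 3], [2, 4], mode="exact")
        assert u == 3.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            u, p = mann_whitney_u(a, b, mode="exact")
            ref = sps.mannwhitneyu(b, a, alternative="two-sided", method="exact")
            assert u == ref.statistic
            assert p == pytest.approx(ref.pvalue)

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 6, 30).astype(float)  # heavy ties
        b = rng.integers(1, 7, 25).astype(float)
        u, p = mann_whitney_u(a, b, mode="normal_approx")
        ref = sps.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            mann_whitney_u([], [1.0])


class TestRankStatistics:
    def test_spearman_examples(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_spearman_matches_scipy_with_ties(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 5, 40).astype(float)
        y = x + rng.integers(0, 3, 40)
        assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_spearman_errors(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 2], [1, 2])

    def test_roc_examples(self):
        assert roc_auc([1, 2, 3, 4], [False, False, True, True]) == 1.0
        assert roc_auc([5, 5, 5, 5], [False, True, False, True]) == 0.5
        assert roc_auc([0.1, 0.2, 0.3, 0.4], [False, True, False, True]) == 0.75

    def test_roc_negation_complement_and_u_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores = rng.normal(size=30)  # continuous: no ties
            labels = rng.random(30) < 0.5
            if labels.all() or not labels.any():
                continue
            auc = roc_auc(scores, labels)
            assert roc_auc(-scores, labels) == pytest.approx(1.0 - auc)
            u, _ = mann_whitney_u(scores[~labels], scores[labels], mode="normal_approx")
            assert auc == pytest.approx(u / (labels.sum() * (~labels).sum()))

    def test_roc_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1.0, 2.0], [True, True])

    def test_agreement(self):
        assert agreement(["a", "b"], ["a", "b"])[0] == 1.0
        assert agreement(["a", "b"], ["b", "a"])[0] == 0.0
        prop, (lo, hi) = agreement(list("a" * 39 + "b" * 9), list("a" * 39 + "c" * 9))
        assert prop == pytest.approx(0.8125)
        # exact binomial (Clopper-Pearson) bounds for 39/48
        assert lo == pytest.approx(sps.beta.ppf(0.025, 39, 10))
        assert hi == pytest.approx(sps.beta.ppf(0.975, 40, 9))
        with pytest.raises(ContractError):
            agreement(["a"], ["a", "b"])


def golden_section_cox_beta(durations, events, z):
    """Brute-force maximizer of the (no-ties) Cox partial likelihood."""

    def neg_log_pl(beta):
        order = np.argsort(durations)
        d, e, x = durations[order], events[order], z[order]
        ll = 0.0
        for i in range(len(d)):
            if e[i]:
                risk = x[i:]  # all with duration >= d[i]
                ll += beta * x[i] - math.log(np.exp(beta * risk).sum())
        return -ll

    lo, hi = -5.0, 5.0
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    for _ in range(200):
        if neg_log_pl(c) < neg_log_pl(d):
            b = d
        else:
            a = c
        c, d = b - phi * (b - a), a + phi * (b - a)
    return (a + b) / 2


class TestCox:
    def test_matches_brute_force_partial_likelihood(self):
        # two groups, distinct event times, no censoring
        cohort = make_cohort(
            rp_grade=[1] * 6,
            time_to_rp_days=[10.0, 25.0, 40.0, 15.0, 55.0, 70.0],
            dose_gy=[60.0, 60.0, 60.0, 40.0, 40.0, 40.0],
        )
        cohort.df["high_dose"] = (cohort.df["dose_gy"] >= 50).astype(float)
        fit = fit_cox_ph(cohort, ["high_dose"], "rp_ge1")
        surv = cohort.survival_frame("rp_ge1")
        beta_star = golden_section_cox_beta(
            surv["duration"].to_numpy(), surv["event"].to_numpy().astype(bool),
            cohort.df["high_dose"].to_numpy(),
        )
        assert fit.loc[0, "coef"] == pytest.approx(beta_star, abs=1e-4)

    def test_constant_covariate_flagged(self):
        cohort = make_cohort(rp_grade=[1, 1, 0, 0, 0, 0],
                             time_to_rp_days=[10.0, 20.0] + [np.nan] * 4)
        fit = fit_cox_ph(cohort, ["v5"], "rp_ge1")
        assert fit.loc[0, "flag"] == "non_identifiable"
        assert fit.loc[0, "coef"] == 0.0

    def test_separation_flagged(self):
        # events only in the high-dose group -> monotone likelihood
        cohort = make_cohort(
            rp_grade=[1, 1, 1, 0, 0, 0],
            time_to_rp_days=[10.0, 20.0, 30.0] + [np.nan] * 3,
            dose_gy=[70.0, 71.0, 72.0, 30.0, 31.0, 32.0],
        )
        cohort.df["high_dose"] = (cohort.df["dose_gy"] >= 50).astype(float)
        fit = fit_cox_ph(cohort, ["high_dose"], "rp_ge1")
        assert fit.loc[0, "flag"] != ""

    def test_no_events_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_cox_ph(make_cohort(), ["dose_gy"], "rp_ge1")


class TestCumulativeIncidence:
    def test_reaches_one_without_censoring(self):
        cohort = make_cohort(n=2, rp_grade=[1, 1], time_to_rp_days=[10.0, 20.0],
                             sample_id=["a", "b"])
        curves = cumulative_incidence(cohort, ["all", "all"], "rp_ge1")
        curve = curves["all"]
        assert curve["incidence"].iloc[0] == 0.0
        assert curve.loc[curve["time"] == 20.0, "incidence"].iloc[0] == pytest.approx(1.0)

    def test_no_events_flat_zero(self):
        curves = cumulative_incidence(make_cohort(), ["all"] * 6, "rp_ge1")
        assert (curves["all"]["incidence"] == 0.0).all()

    def test_hand_km_with_censoring(self):
        cohort = make_cohort(
            n=3, sample_id=["a", "b", "c"], rp_grade=[1, 1, 0],
            time_to_rp_days=[10.0, 30.0, np.nan], followup_days=[90.0, 90.0, 20.0],
        )
        curve = cumulative_incidence(cohort, ["x"] * 3, "rp_ge1")["x"]
        by_time = dict(zip(curve["time"], curve["incidence"]))
        assert by_time[10.0] == pytest.approx(1 / 3)
        # after censoring at 20, risk set at 30 is one patient -> survival 0
        assert by_time[30.0] == pytest.approx(1.0)

    def test_monotone_and_matches_ecdf_without_censoring(self):
        rng = np.random.default_rng(8)
        times = rng.uniform(5, 85, 12).round(1)
        cohort = make_cohort(n=12, rp_grade=[2] * 12, time_to_rp_days=times,
                             sample_id=[f"s{i}" for i in range(12)])
        curve = cumulative_incidence(cohort, ["x"] * 12, "rp_ge1")["x"]
        inc = curve["incidence"].to_numpy()
        assert (np.diff(inc) >= -1e-12).all()
        assert inc.min() >= 0.0 and inc.max() <= 1.0
        for t, v in zip(curve["time"], inc):
            assert v == pytest.approx((times <= t).mean())


class TestAssociationTables:
    def test_reconstructed_cohort_reproduces_published_chi2(self):
        tables = build_association_tables(reconstruct_paper_cohort())
        expected = {
            "rp_ge1": {"sex": 1.505, "age": 2.231, "smoking": 0.762,
                       "chemotherapy": 0.000, "pathology": 2.385},
            "rp_ge2": {"sex": 0.680, "age": 4.179, "smoking": 5.829,
                       "chemotherapy": 1.621, "pathology": 2.826},
            "rp_ge3": {"sex": 1.399, "age": 1.994, "smoking": 6.374,
                       "chemotherapy": 0.745, "pathology": 0.686},
        }
        for event, stats in expected.items():
            got = tables[event].drop_duplicates("covariate").set_index("covariate")
            for covariate, value in stats.items():
                assert got.loc[covariate, "chi2"] == pytest.approx(value, abs=5e-4), (
                    event, covariate
                )

    def test_no_events_degenerate(self):
        with pytest.raises(DegenerateInputError):
            build_association_tables(make_cohort())

    def test_synthetic_cohort_tables_have_valid_structure(self):
        from rpflux.synthetic_cohort import SimulationConfig, generate_map, generate_cohort

        cfg = SimulationConfig(seed=11)
        _, cohort, _ = generate_cohort(cfg, generate_map(cfg))
        tables = build_association_tables(cohort)
        assert set(tables) == {"rp_ge1", "rp_ge2", "rp_ge3"}
        for event, table in tables.items():
            n_cases = int(cohort.event_indicator(event).sum())
            for cov, sub in table.groupby("covariate"):
                assert sub["n_case"].sum() == n_cases
                assert (sub["n_case"] + sub["n_control"]).sum() == len(cohort)
                assert sub["chi2"].nunique() == 1
                assert 0.0 <= sub["p"].iloc[0] <= 1.0
                assert sub["df"].iloc[0] == len(sub) - 1


class TestEvaluatePredictions:
    def test_perfect_agreement(self):
        cohort = make_cohort(
            rp_grade=[0, 0, 1, 2, 3, 4],
            time_to_rp_days=[np.nan, np.nan, 20.0, 30.0, 40.0, 50.0],
        )
        scores = pd.DataFrame({
            "sample_id": cohort.df["sample_id"],
            "s_value": [-1.0, -0.5, 0.2, 0.4, 1.0, 2.0],
            "predicted_class": ["none", "none", "grade_le2", "grade_le2",
                                "grade_ge3", "grade_ge3"],
        })
        report = evaluate_predictions(scores, cohort)
        assert report["agreement"] == 1.0
        assert report["spearman_rho"] == pytest.approx(
            spearman_rho([0, 0, 1, 1, 2, 2], [0, 0, 1, 2, 3, 4])
        )
        assert report["auc_s_vs_rp"] == 1.0

    def test_id_mismatch_rejected(self):
        cohort = make_cohort()
        scores = pd.DataFrame({
            "sample_id": ["zz"], "s_value": [0.1], "predicted_class": ["none"],
        })
        with pytest.raises(ContractError, match="zz"):
            evaluate_predictions(scores, cohort)


class TestCohortTableValidation:
    def test_grade_time_consistency_enforced(self):
        with pytest.raises(ContractError, match="time_to_rp"):
            make_cohort(rp_grade=[1] * 6)  # grade >=1 but no onset time

    def test_followup_before_event_rejected(self):
        with pytest.raises(ContractError, match="followup"):
            make_cohort(rp_grade=[1] + [0] * 5,
                        time_to_rp_days=[50.0] + [np.nan] * 5,
                        followup_days=[30.0] + [90.0] * 5)
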