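"""Outcome statistics: protocol scoring, paired ANOVA, Wilcoxon/BH, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from affectkit.analytics import (
    AnalysisConfig,
    SchemaError,
    analyze_cohort,
    bh_adjust,
    make_egg_protocol,
    pearson_assoc,
    rm_anova_two_timepoints,
    score_egg,
    srs2_severity_class,
    study_compliance,
    summarize_change,
    wilcoxon_item_tests,
    write_report,
    yes_fraction,
)
from affectkit.labels import EMOTIONS
from affectkit.synthetic import CohortGenParams, generate_cohort


class TestEggProtocol:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_structure_forty_items_five_each(self, seed):
        p = make_egg_protocol(seed)
        assert len(p) == 40
        assert all(p.count(e) == 5 for e in EMOTIONS)

    def test_same_seed_same_order(self):
        assert make_egg_protocol(7) == make_egg_protocol(7)

    def test_different_seeds_differ(self):
        pairs = [(make_egg_protocol(i), make_egg_protocol(100 + i)) for i in range(10)]
        assert any(a != b for a, b in pairs)  # permutation space is astronomical
        assert sum(a != b for a, b in pairs) >= 9

    def test_perfect_score(self):
        p = make_egg_protocol(0)
        assert score_egg(p, p) == 40

    def test_constant_guessing_scores_per_emotion_count(self):
        p = make_egg_protocol(0)
        assert score_egg(["happy"] * 40, p) == 5

    def test_alias_canonicalization_in_scoring(self):
        p = ["neutral", "contempt", "scared"]
        assert score_egg(["calm", "meh", "afraid"], p) == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_egg(["happy"] * 39, make_egg_protocol(0))

    def test_random_guessing_matches_positionwise_oracle(self, rng):
        p = make_egg_protocol(1)
        guesses = list(rng.choice(EMOTIONS, 40))
        oracle = sum(g == t for g, t in zip(guesses, p))
        assert score_egg(guesses, p) == oracle

    def test_uniform_guessing_expected_score_is_five(self):
        p = make_egg_protocol(2)
        rng = np.random.default_rng(0)
        scores = [
            score_egg(rng.choice(EMOTIONS, 40), p) for _ in range(10_000)
        ]
        assert np.mean(scores) == pytest.approx(5.0, abs=0.2)


class TestSeverityBands:
    @pytest.mark.parametrize(
        "score,band",
        [(59, "normal"), (59.99, "normal"), (60, "mild"), (65, "mild"),
         (65.01, "moderate"), (75, "moderate"), (75.01, "severe"), (80.07, "severe")],
    )
    def test_band_assignment(self, score, band):
        assert srs2_severity_class(score) == band

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            srs2_severity_class(float("nan"))


class TestRmAnova:
    def test_constant_differences_are_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            rm_anova_two_timepoints([1, 2, 3], [2, 3, 4])

    def test_matches_hand_paired_t_formula(self):
        x = np.array([10.0, 12, 14, 16])
        y = np.array([11.0, 12, 15, 18])
        d = y - x
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        res = rm_anova_two_timepoints(x, y)
        assert res.F == pytest.approx(t_hand**2, abs=1e-9)
        assert (res.df1, res.df2) == (1, 3)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), 3), abs=1e-12)

    def test_f_equals_squared_paired_t_on_random_data(self, rng):
        for _ in range(20):
            n = rng.integers(4, 30)
            x = rng.normal(size=n)
            y = x + rng.normal(0.3, 1.0, size=n)
            res = rm_anova_two_timepoints(x, y)
            t = stats.ttest_rel(y, x)
            assert res.F == pytest.approx(t.statistic**2, abs=1e-9)
            assert res.p == pytest.approx(t.pvalue, abs=1e-12)

    def test_agrees_with_pingouin_rm_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 14
        x = rng.normal(80, 9, n)
        y = x - 7 + rng.normal(0, 4, n)
        res = rm_anova_two_timepoints(x, y)
        df = pd.DataFrame(
            {
                "score": np.concatenate([x, y]),
                "time": ["intake"] * n + ["conclusion"] * n,
                "subject": list(range(n)) * 2,
            }
        )
        aov = pg.rm_anova(dv="score", within="time", subject="subject", data=df)
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)

    def test_type_i_error_under_null(self):
        # null paired generator at the study's n: rejection rate near alpha
        rng = np.random.default_rng(0)
        n, reps, alpha = 14, 2000, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.normal(80, 9.5, n)
            y = x + rng.normal(0.0, 4.6, n)
            if rm_anova_two_timepoints(x, y).p < alpha:
                rejections += 1
        assert 0.037 <= rejections / reps <= 0.063

    def test_sem_identity(self, rng):
        x = rng.normal(size=14)
        y = x + rng.normal(1, 1, 14)
        res = rm_anova_two_timepoints(x, y)
        assert res.sem_intake == pytest.approx(res.sd_intake / np.sqrt(14))


def _exact_signed_rank_p(d):
    """Enumerate all 2^n sign assignments of the |d| ranks (no ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    W = ranks[d > 0].sum()
    total = ranks.sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, total - w) <= min(W, total - W):
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_identical_matrices_all_degenerate_p1(self, rng):
        X = rng.integers(1, 5, (14, 65))
        res = wilcoxon_item_tests(X, X.copy())
        assert (res["p_raw"] == 1.0).all()
        assert res["degenerate"].all()

    def test_uniform_unit_shift_is_highly_significant(self, rng):
        X = rng.integers(2, 5, (14, 65))
        Y = X.copy()
        Y[:, 10] = X[:, 10] - 1
        res = wilcoxon_item_tests(X, Y)
        assert res.loc[res["item_id"] == 11, "p_raw"].iloc[0] < 0.001

    def test_mean_change_column(self, rng):
        X = rng.integers(1, 5, (10, 65)).astype(float)
        Y = rng.integers(1, 5, (10, 65)).astype(float)
        res = wilcoxon_item_tests(X, Y)
        assert np.allclose(res["mean_change"], Y.mean(axis=0) - X.mean(axis=0))
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()

    def test_exact_path_matches_enumeration_oracle(self, rng):
        # continuous differences, n <= 10: exact distribution by enumeration
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = r.normal(0.4, 1.0, 9)
            X = np.zeros((9, 1))
            Y = d.reshape(-1, 1)
            p = wilcoxon_item_tests(X, Y)["p_raw"].iloc[0]
            assert p == pytest.approx(_exact_signed_rank_p(d), abs=1e-12)

    def test_rank_sum_variant_runs_and_flags_degenerate(self, rng):
        X = rng.integers(1, 5, (12, 3)).astype(float)
        Y = X + 1
        res = wilcoxon_item_tests(X, Y, variant="rank_sum")
        assert (res["p_raw"] < 1).all()
        Z = np.full((12, 3), 2.0)
        res2 = wilcoxon_item_tests(Z, Z, variant="rank_sum")
        assert (res2["p_raw"] == 1.0).all() and res2["degenerate"].all()

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError):
            wilcoxon_item_tests(np.ones((4, 2)), np.ones((4, 2)), variant="median")

    def test_study_conditions_item_change_usually_significant(self):
        """Item shifting from mean ~2.9 to ~2.1 at n = 14: the median
        simulated raw p across replicates falls under .05."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(500):
            lat_in = rng.normal(0.55, 1.0, 14)
            lat_out = lat_in - 1.05 + rng.normal(0, 0.6, 14)
            X = np.clip(np.round(2.5 + 0.8 * lat_in), 1, 4).reshape(-1, 1)
            Y = np.clip(np.round(2.5 + 0.8 * lat_out), 1, 4).reshape(-1, 1)
            if np.all(X == Y):
                ps.append(1.0)
                continue
            ps.append(wilcoxon_item_tests(X, Y)["p_raw"].iloc[0])
        assert np.median(ps) < 0.05


def _bh_oracle(p):
    """Brute-force step-up: sort, p_(i)·m/i, enforce monotone from the top, cap."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(p[i] * m / rank, prev)
        adj[i] = val
        prev = val
    return np.minimum(adj, 1.0)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_oracle_on_all_subsets(self, rng):
        base = rng.uniform(0, 1, 6)
        for r in range(1, 7):
            for idx in itertools.combinations(range(6), r):
                sub = base[list(idx)]
                assert np.allclose(bh_adjust(sub), _bh_oracle(sub), atol=1e-12)

    def test_never_decreases_elementwise(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # step-up is monotone: smaller raw p never gets a larger adjusted p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12), st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        p = np.asarray(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_assoc(x, x)
        assert r == 1.0 and p == 0.0

    def test_perfect_negative_affine(self):
        x = np.arange(14.0)
        r, p = pearson_assoc(x, -2 * x + 3)
        assert r == -1.0

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=14)
        y = 0.5 * x + rng.normal(size=14)
        r, p = pearson_assoc(x, y)
        rx = (x - x.mean()) / x.std()
        ry = (y - y.mean()) / y.std()
        r_hand = (rx * ry).mean()
        t_hand = r_hand * np.sqrt(12 / (1 - r_hand**2))
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 12), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_assoc(np.ones(5), np.arange(5.0))


class TestSummaries:
    def test_sem_is_sd_over_sqrt_n(self, rng):
        x = rng.normal(80, 9, 14)
        y = x - 7
        s = summarize_change(x, y)
        assert s["sem_intake"] == pytest.approx(s["sd_intake"] / np.sqrt(14), abs=1e-12)

    def test_no_change_no_movers(self, rng):
        x = rng.normal(80, 9, 10)
        s = summarize_change(x, x.copy())
        assert s["mean_change"] == 0.0 and s["n_class_improved"] == 0

    def test_matches_arithmetic_oracle(self, rng):
        x = rng.normal(75, 10, 20)
        y = x - rng.normal(5, 3, 20)
        s = summarize_change(x, y)
        assert s["mean_intake"] == pytest.approx(np.sum(x) / 20)
        assert s["sd_conclusion"] == pytest.approx(
            np.sqrt(np.sum((y - y.mean()) ** 2) / 19)
        )
        assert s["mean_change"] == pytest.approx(y.mean() - x.mean())

    def test_severity_improvement_counted(self):
        x = [80, 70, 62, 55]  # severe, moderate, mild, normal
        y = [70, 62, 55, 55]  # each of the first three moves down one band
        assert summarize_change(x, y)["n_class_improved"] == 3

    def test_interview_fraction(self):
        assert yes_fraction(12, 14) == pytest.approx(85.714285, abs=1e-4)

    def test_compliance_arithmetic(self):
        statuses = ["withdrew"] * 5 + ["noncompliant"] * 5 + ["compliant"] * 14
        rep = study_compliance(statuses)
        assert rep["n_eligible"] == 19
        assert rep["compliance_rate_percent"] == pytest.approx(100 * 14 / 19)


class TestAnalyzeCohort:
    def test_calibrated_cohort_round_trip(self):
        df = generate_cohort(CohortGenParams(rng_seed=1))
        rep = analyze_cohort(df)
        total = rep["srs2_anova"]["total"]
        sem = 9.53 / np.sqrt(14)
        assert abs(total["mean_intake"] - 80.07) < 2 * sem
        assert abs(total["mean_conclusion"] - 72.93) < 2 * 10.29 / np.sqrt(14)
        assert rep["egg_anova"]["n"] == 11

    def test_missing_columns_schema_error(self):
        with pytest.raises(SchemaError, match="missing"):
            analyze_cohort(pd.DataFrame({"participant_id": ["a"]}))

    def test_empty_table_schema_error(self):
        with pytest.raises(SchemaError):
            analyze_cohort(pd.DataFrame())

    def test_null_cohort_subscales_rarely_significant(self):
        """Specificity: under a null generator the correlated subscale family
        produces no significant ANOVA in >= 90% of seeded runs."""
        hits = 0
        runs = 60
        for seed in range(runs):
            df = generate_cohort(
                CohortGenParams(n_participants=14, srs2_mean_change=0.0, rng_seed=seed)
            )
            rep = analyze_cohort(df)
            any_sig = any(r["p"] < 0.05 for r in rep["srs2_anova"].values())
            hits += not any_sig
        assert hits / runs >= 0.90

    def test_report_files_written(self, tmp_path):
        df = generate_cohort(CohortGenParams(rng_seed=3))
        rep = analyze_cohort(df)
        write_report(rep, tmp_path)
        assert (tmp_path / "report.json").exists()
        md = (tmp_path / "report.md").read_text()
        assert "SRS-2" in md and "F(1,13)" in md
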