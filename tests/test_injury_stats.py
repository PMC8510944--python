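"""Cohort parsing and the study's statistical toolkit, with brute-force and
independent-library oracles."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from blasttube import injury_stats as ist


class TestParseCohort:
    def test_packaged_fixture_counts(self, cohort):
        assert len(cohort) == 17
        assert sum(r.armor for r in cohort) == 6
        assert sum(not r.armor for r in cohort) == 11
        assert not cohort.unknown_remarks

    def test_death_implies_arrest(self, cohort):
        for r in cohort:
            if r.died:
                assert r.respiratory_arrest

    def test_mean_body_weight(self, cohort):
        mean = np.mean([r.body_weight for r in cohort])
        assert round(mean) == 38

    def test_organ_flag_parsing(self, cohort):
        by_id = {r.animal_id: r for r in cohort}
        assert by_id[12].organ_flags == frozenset({"LH"})
        # the 'Splenic & Liver injury' remark must yield both flags
        assert {"splenic", "liver", "BR", "IAH", "LH"} <= by_id[17].organ_flags
        assert "hemothorax" in by_id[1].organ_flags

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("id,body_weight_kg,body_armor,organ_damage,"
                     "respiratory_arrest,outcome\n")
        c = ist.parse_cohort(p)
        assert len(c) == 0

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,body_weight_kg\n1,38\n")
        with pytest.raises(ValueError, match="missing required columns"):
            ist.parse_cohort(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("id,body_weight_kg,body_armor,organ_damage,"
                     "respiratory_arrest,outcome\n"
                     "1,38,No,LH,No,Survival\n1,40,No,LH,No,Survival\n")
        with pytest.raises(ValueError, match="duplicate"):
            ist.parse_cohort(p)

    def test_single_row_flags(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("id,body_weight_kg,body_armor,organ_damage,"
                     "respiratory_arrest,outcome\n"
                     "12,36,Yes,LH,No,Survival\n")
        c = ist.parse_cohort(p)
        r = c.records[0]
        assert r.organ_flags == frozenset({"LH"})
        assert r.armor and not r.respiratory_arrest and not r.died


class TestTabulate:
    def test_arrest_by_outcome(self, cohort):
        t = ist.tabulate(cohort, lambda r: r.respiratory_arrest,
                         lambda r: r.died)
        assert t.array.tolist() == [[9, 0], [3, 5]]
        assert t.margins["total"] == 17

    def test_armor_by_outcome(self, cohort):
        t = ist.tabulate(cohort, lambda r: not r.armor, lambda r: r.died)
        assert t.array.tolist() == [[6, 0], [6, 5]]

    def test_empty_cohort_all_zero(self):
        with pytest.raises(ValueError):
            # an all-zero table is rejected by the table invariant
            ist.tabulate(ist.Cohort(records=[]), lambda r: True,
                         lambda r: True)


def brute_force_fisher(a, b, c, d):
    """Enumeration oracle: sum hypergeometric probabilities of all tables
    with the observed margins that are no more probable than observed."""
    from math import comb

    r0, r1 = a + b, c + d
    c0 = a + c
    n = r0 + r1
    denom = comb(n, c0)

    def prob(x):
        return comb(r0, x) * comb(r1, c0 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c0 - r1), min(r0, c0) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_arrest_outcome_p_value(self, cohort):
        t = ist.tabulate(cohort, lambda r: r.respiratory_arrest,
                         lambda r: r.died)
        res = ist.fisher_exact_two_sided(t)
        assert round(res.p_value, 3) == 0.009

    def test_balanced_table_p_one(self):
        res = ist.fisher_exact_two_sided(
            ist.ContingencyTable2x2(5, 5, 5, 5))
        assert res.p_value == pytest.approx(1.0)

    @given(st.tuples(st.integers(0, 8), st.integers(0, 8),
                     st.integers(0, 8), st.integers(0, 8))
           .filter(lambda t: 1 <= sum(t) <= 20))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        table = ist.ContingencyTable2x2(a, b, c, d)
        res = ist.fisher_exact_two_sided(table)
        if res.degenerate:
            assert 0 in (a + b, c + d, a + c, b + d)
            return
        assert res.p_value == pytest.approx(
            brute_force_fisher(a, b, c, d), abs=1e-12)

    @given(st.tuples(st.integers(1, 6), st.integers(1, 6),
                     st.integers(1, 6), st.integers(1, 6)))
    def test_invariant_to_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        p0 = ist.fisher_exact_two_sided(
            ist.ContingencyTable2x2(a, b, c, d)).p_value
        p_row = ist.fisher_exact_two_sided(
            ist.ContingencyTable2x2(c, d, a, b)).p_value
        p_col = ist.fisher_exact_two_sided(
            ist.ContingencyTable2x2(b, a, d, c)).p_value
        assert p_row == pytest.approx(p0, rel=1e-10)
        assert p_col == pytest.approx(p0, rel=1e-10)

    def test_agrees_with_scipy(self, cohort):
        t = ist.tabulate(cohort, lambda r: r.respiratory_arrest,
                         lambda r: r.died)
        _, p_ref = sps.fisher_exact(t.array, alternative="two-sided")
        assert ist.fisher_exact_two_sided(t).p_value == \
            pytest.approx(p_ref, rel=1e-9)

    def test_degenerate_margin_flagged(self):
        res = ist.fisher_exact_two_sided(ist.ContingencyTable2x2(0, 0, 3, 5))
        assert res.degenerate and res.p_value == 1.0


class TestSurvivalSummary:
    def test_fixture_summary(self, cohort):
        s = ist.survival_summary(cohort)
        assert s.survival_percent == {"armor": 100, "no_armor": 55}
        assert s.survival_fraction["no_armor"] == pytest.approx(6 / 11)
        assert s.organ_counts["LH"] == 17
        assert s.n_arrest == 8
        assert s.n_arrest_recovered == 3
        assert round(s.mean_body_weight) == 38

    def test_splenic_with_iah_count(self, cohort):
        n = sum(1 for r in cohort
                if {"splenic", "IAH"} <= r.organ_flags)
        assert n == 14

    def test_rounding_half_away_from_zero(self):
        # 6/11 = 54.54... -> 55
        assert ist._round_half_away(100 * 6 / 11) == 55
        assert ist._round_half_away(54.5) == 55
        assert ist._round_half_away(54.49) == 54


def make_long(y, labels, times=None):
    reps, N, T = 1, *y.shape
    rows = []
    for s in range(N):
        for t in range(T):
            rows.append((s, f"g{labels[s]}",
                         t if times is None else times[t], y[s, t]))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "value"])


class TestRepeatedMeasuresAnova:
    def test_identical_groups_zero_group_f(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(5, 4))
        y = np.vstack([block, block])  # group 2 duplicates group 1
        labels = np.array([0] * 5 + [1] * 5)
        res = ist.repeated_measures_anova(make_long(y, labels))
        assert res.f_group == pytest.approx(0.0, abs=1e-20)

    def test_brute_force_cell_means_oracle(self):
        """F statistics agree with a direct from-scratch computation of the
        split-plot sums of squares on a random balanced design."""
        rng = np.random.default_rng(7)
        N, T = 8, 4
        y = rng.normal(size=(N, T)) + np.arange(T) * 0.3
        labels = np.array([0] * 4 + [1] * 4)
        res = ist.repeated_measures_anova(make_long(y, labels))

        mu = y.mean()
        m_s = y.mean(axis=1)
        m_t = y.mean(axis=0)
        m_g = np.array([y[labels == g].mean() for g in (0, 1)])
        m_gt = np.array([y[labels == g].mean(axis=0) for g in (0, 1)])
        n_g = np.array([4, 4])
        ss_group = T * np.sum(n_g * (m_g - mu) ** 2)
        ss_subj = T * np.sum((m_s - mu) ** 2) - ss_group
        ss_time = N * np.sum((m_t - mu) ** 2)
        ss_cells = np.sum(n_g[:, None] * (m_gt - mu) ** 2)
        ss_inter = ss_cells - ss_group - ss_time
        ss_within = np.sum((y - m_s[:, None]) ** 2)
        ss_err = ss_within - ss_time - ss_inter
        f_group = (ss_group / 1) / (ss_subj / (N - 2))
        f_time = (ss_time / (T - 1)) / (ss_err / ((N - 2) * (T - 1)))
        f_inter = (ss_inter / (T - 1)) / (ss_err / ((N - 2) * (T - 1)))
        assert res.f_group == pytest.approx(f_group, rel=1e-9)
        assert res.f_time == pytest.approx(f_time, rel=1e-9)
        assert res.f_interaction == pytest.approx(f_inter, rel=1e-9)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        N, T = 10, 5
        y = rng.normal(size=(N, T))
        y[5:] += 0.8  # group effect
        labels = np.array([0] * 5 + [1] * 5)
        df = make_long(y, labels)
        res = ist.repeated_measures_anova(df)
        aov = pingouin.mixed_anova(data=df, dv="value", within="time",
                                   between="group", subject="subject")
        f_ping = {row["Source"]: row["F"] for _, row in aov.iterrows()}
        assert res.f_group == pytest.approx(f_ping["group"], rel=1e-6)
        assert res.f_time == pytest.approx(f_ping["time"], rel=1e-6)
        assert res.f_interaction == pytest.approx(f_ping["Interaction"],
                                                  rel=1e-6)

    def test_type_one_error_calibrated(self):
        """Null generator: the group test rejects at ~5% (2000 reps)."""
        rng = np.random.default_rng(42)
        y = rng.normal(size=(2000, 12, 5))
        labels = np.array([0] * 6 + [1] * 6)
        _, p = ist.split_plot_group_f(y, labels)
        assert 0.03 <= np.mean(p < 0.05) <= 0.07

    def test_vectorised_path_matches_scalar(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(4, 8, 3))
        labels = np.array([0] * 4 + [1] * 4)
        F, _ = ist.split_plot_group_f(y, labels)
        for k in range(4):
            res = ist.repeated_measures_anova(make_long(y[k], labels))
            assert res.f_group == pytest.approx(F[k], rel=1e-10)

    def test_greenhouse_geisser_option(self):
        """GG correction: epsilon in (1/(T-1), 1], within-subject p-values
        no smaller than uncorrected ones."""
        rng = np.random.default_rng(11)
        N, T = 10, 5
        y = rng.normal(size=(N, T))
        y += np.cumsum(rng.normal(size=(N, T)) * 0.5, axis=1)  # non-spheric
        labels = np.array([0] * 5 + [1] * 5)
        df = make_long(y, labels)
        plain = ist.repeated_measures_anova(df)
        gg = ist.repeated_measures_anova(df, correction="gg")
        eps = gg.df["gg_epsilon"]
        assert 1.0 / (T - 1) <= eps <= 1.0
        assert gg.f_time == plain.f_time        # only the df change
        assert gg.p_group == plain.p_group      # between test untouched
        assert gg.p_time != plain.p_time
        with pytest.raises(ValueError):
            ist.repeated_measures_anova(df, correction="huynh")

    def test_incomplete_subjects_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(6, 3))
        labels = np.array([0, 0, 0, 1, 1, 1])
        df = make_long(y, labels)
        df = df[~((df.subject == 0) & (df.time > 0))]  # subject 0: 1 point
        with pytest.warns(UserWarning, match="incomplete"):
            res = ist.repeated_measures_anova(df)
        assert res.excluded_subjects == (0,)


class TestTwoGroupT:
    def test_identical_groups(self):
        res = ist.two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_separation_limit(self):
        a = np.array([1.0, 2.0, 3.0])
        res = ist.two_group_t(a, a + 1e3 + np.array([1e-6, -1e-6, 0.0]))
        assert res.p_value < 1e-6

    def test_closed_form_3_plus_3(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([2.0, 5.0, 6.0])
        df = 4
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / df
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        res = ist.two_group_t(a, b)
        assert res.t == pytest.approx(t_expected, rel=1e-12)
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(abs(t_expected), df), rel=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(0.5, 1.0, size=9)
        res = ist.two_group_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_conventions(self):
        res = ist.two_group_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0 and res.flagged
        res2 = ist.two_group_t([2.0, 2.0], [3.0, 3.0])
        assert res2.p_value == 0.0 and res2.flagged

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            ist.two_group_t([1.0], [1.0, 2.0])
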