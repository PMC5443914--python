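import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from painsim.errors import ContractViolation, UsageError
from painsim.instruments import (
    ResponseSheet,
    compare_pre_post,
    cronbach_alpha,
    kr20,
    median_iqr,
    reverse_key,
    score_attrakdiff,
    score_likert,
    score_proportion_correct,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------
# bundled instrument definitions
# ---------------------------------------------------------------------


class TestBundledSpecs:
    def test_attrakdiff_shape(self, attrakdiff_spec):
        assert len(attrakdiff_spec.items) == 28
        assert attrakdiff_spec.scale_min == 1 and attrakdiff_spec.scale_max == 7
        assert set(attrakdiff_spec.subscales) == {"PQ", "HQI", "HQS", "ATT"}
        for sub in attrakdiff_spec.subscales:
            assert sum(1 for i in attrakdiff_spec.items if i.subscale == sub) == 7

    def test_popmgs_shape(self, popmgs_spec):
        assert len(popmgs_spec.items) == 12
        assert (popmgs_spec.scale_min, popmgs_spec.scale_max) == (0, 5)

    def test_bq2_shape(self, bq2_spec):
        assert len(bq2_spec.items) == 27
        assert (bq2_spec.scale_min, bq2_spec.scale_max) == (0, 5)
        assert len(bq2_spec.subscales) == 4

    def test_pak_shape(self, pak_spec):
        assert len(pak_spec.items) == 15
        assert pak_spec.n_options == 6
        for item in pak_spec.items:
            assert 1 <= item.correct <= 5  # option 6 ("do not know") never correct


# ---------------------------------------------------------------------
# semantic differential
# ---------------------------------------------------------------------


def _sheet(spec, answers, **kw):
    return ResponseSheet(respondent="r1", instrument=spec.name, answers=answers, **kw)


class TestAttrakdiff:
    def test_middle_step_scores_zero(self, attrakdiff_spec):
        sheet = _sheet(attrakdiff_spec, {i: 4 for i in attrakdiff_spec.item_ids})
        res = score_attrakdiff(sheet, attrakdiff_spec)
        assert all(v == 0.0 for v in res.subscales.values())

    def test_positive_pole_scores_three(self, attrakdiff_spec):
        answers = {
            item.id: (1 if item.reverse else 7) for item in attrakdiff_spec.items
        }
        res = score_attrakdiff(_sheet(attrakdiff_spec, answers), attrakdiff_spec)
        assert res.subscales == {"PQ": 3.0, "HQI": 3.0, "HQS": 3.0, "ATT": 3.0}

    def test_mixed_sheet_matches_arithmetic_oracle(self, attrakdiff_spec):
        rng = np.random.default_rng(5)
        for _ in range(20):
            answers = {i: int(rng.integers(1, 8)) for i in attrakdiff_spec.item_ids}
            res = score_attrakdiff(_sheet(attrakdiff_spec, answers), attrakdiff_spec)
            for sub in attrakdiff_spec.subscales:
                vals = []
                for item in attrakdiff_spec.items:
                    if item.subscale != sub:
                        continue
                    raw = answers[item.id]
                    vals.append((4 - raw) if item.reverse else (raw - 4))
                assert res.subscales[sub] == pytest.approx(sum(vals) / len(vals))

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(deadline=None, max_examples=50)
    def test_scores_bounded(self, attrakdiff_spec, seed):
        rng = np.random.default_rng(seed)
        answers = {i: int(rng.integers(1, 8)) for i in attrakdiff_spec.item_ids}
        res = score_attrakdiff(_sheet(attrakdiff_spec, answers), attrakdiff_spec)
        assert all(-3.0 <= v <= 3.0 for v in res.subscales.values())

    def test_missing_item_warns_and_excludes(self, attrakdiff_spec):
        answers = {i: 7 for i in attrakdiff_spec.item_ids}
        del answers["pq2"]
        with pytest.warns(UserWarning, match="missing"):
            res = score_attrakdiff(_sheet(attrakdiff_spec, answers), attrakdiff_spec)
        assert res.missing == ["pq2"]
        # pq2 is not reverse-keyed, so dropping a 7 leaves the PQ mean of +3s...
        # all remaining mapped values for PQ are computed over 6 items
        expected = np.mean([
            -(7 - 4) if i.reverse else (7 - 4)
            for i in attrakdiff_spec.items if i.subscale == "PQ" and i.id != "pq2"
        ])
        assert res.subscales["PQ"] == pytest.approx(expected)

    @given(st.integers(min_value=1, max_value=7))
    @settings(deadline=None)
    def test_reverse_key_involution(self, attrakdiff_spec, raw):
        item = attrakdiff_spec.items[0]
        assert reverse_key(
            attrakdiff_spec, item, reverse_key(attrakdiff_spec, item, raw)
        ) == raw


# ---------------------------------------------------------------------
# multiple choice
# ---------------------------------------------------------------------


class TestProportionCorrect:
    def test_all_correct_is_100(self, pak_spec):
        answers = {i.id: i.correct for i in pak_spec.items}
        res = score_proportion_correct(_sheet(pak_spec, answers), pak_spec)
        assert res.total == 100.0

    def test_all_do_not_know_is_0(self, pak_spec):
        answers = {i.id: 6 for i in pak_spec.items}
        res = score_proportion_correct(_sheet(pak_spec, answers), pak_spec)
        assert res.total == 0.0

    def test_nine_correct_is_60(self, pak_spec):
        answers = {}
        for k, item in enumerate(pak_spec.items):
            answers[item.id] = item.correct if k < 9 else 6
        res = score_proportion_correct(_sheet(pak_spec, answers), pak_spec)
        assert res.total == pytest.approx(60.0)

    def test_unanswered_counts_incorrect_and_flagged(self, pak_spec):
        answers = {i.id: i.correct for i in pak_spec.items}
        answers.pop("k1")
        res = score_proportion_correct(_sheet(pak_spec, answers), pak_spec)
        assert res.missing == ["k1"]
        assert res.total == pytest.approx(100.0 * 14 / 15)

    def test_out_of_scale_answer_rejected(self, pak_spec):
        answers = {i.id: i.correct for i in pak_spec.items}
        answers["k1"] = 7
        with pytest.raises(ContractViolation, match="k1"):
            score_proportion_correct(_sheet(pak_spec, answers), pak_spec)


# ---------------------------------------------------------------------
# likert
# ---------------------------------------------------------------------


class TestLikert:
    def test_all_zero(self, bq2_spec):
        res = score_likert(_sheet(bq2_spec, {i: 0 for i in bq2_spec.item_ids}), bq2_spec)
        assert all(v == 0.0 for v in res.subscales.values())
        assert res.total == 0.0

    def test_all_five(self, bq2_spec):
        res = score_likert(_sheet(bq2_spec, {i: 5 for i in bq2_spec.item_ids}), bq2_spec)
        assert all(v == 5.0 for v in res.subscales.values())

    def test_random_sheet_matches_brute_force(self, bq2_spec):
        rng = np.random.default_rng(8)
        for _ in range(20):
            answers = {i: int(rng.integers(0, 6)) for i in bq2_spec.item_ids}
            res = score_likert(_sheet(bq2_spec, answers), bq2_spec)
            for sub in bq2_spec.subscales:
                vals = [answers[i.id] for i in bq2_spec.items if i.subscale == sub]
                assert res.subscales[sub] == pytest.approx(np.mean(vals))
            assert res.total == pytest.approx(np.mean(list(answers.values())))

    def test_out_of_scale_names_item(self, popmgs_spec):
        answers = {i: 3 for i in popmgs_spec.item_ids}
        answers["p7"] = 9
        with pytest.raises(ContractViolation, match="p7"):
            score_likert(_sheet(popmgs_spec, answers), popmgs_spec)


# ---------------------------------------------------------------------
# median / IQR
# ---------------------------------------------------------------------


class TestMedianIqr:
    def test_singleton(self):
        assert median_iqr([5]) == (5.0, 0.0)

    def test_even_n_midpoint(self):
        med, iqr = median_iqr([1, 2, 3, 4])
        assert med == 2.5
        assert iqr == 2.0  # Tukey hinges: 1.5 and 3.5

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=100)
    def test_matches_order_statistic_oracle(self, values):
        import statistics

        med, iqr = median_iqr(values)
        x = sorted(values)
        n = len(x)
        h = (n + 1) // 2
        lower, upper = x[:h], x[n - h:]
        assert med == pytest.approx(statistics.median(x))
        assert iqr == pytest.approx(
            statistics.median(upper) - statistics.median(lower)
        )

    def test_empty_rejected(self):
        with pytest.raises(ContractViolation):
            median_iqr([])


# ---------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------


def enumeration_oracle(diffs, alternative="two-sided"):
    """Independent exact test: enumerate every sign assignment directly."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    count = 0
    total = 0
    for signs in itertools.product((-1, 1), repeat=len(d)):
        w = float(sum(r for r, s in zip(ranks, signs) if s > 0))
        total += 1
        if alternative == "greater":
            count += w >= w_obs - 1e-9
        elif alternative == "less":
            count += w <= w_obs + 1e-9
        else:
            count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return count / total


class TestWilcoxon:
    def test_all_positive_n6_one_sided(self):
        pre = [1, 2, 3, 4, 5, 6]
        post = [2, 4, 5, 7, 8, 10]
        res = wilcoxon_signed_rank(pre, post, mode="exact", alternative="greater")
        assert res.p == pytest.approx(1 / 64)
        assert res.w_plus == 21.0 and res.w_minus == 0.0

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p == 1.0
        assert res.method == "degenerate"
        assert np.isnan(res.w_plus)

    def test_negation_flips_z_same_two_sided_p(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(size=12)
        post = pre + rng.normal(0.5, 1, size=12)
        a = wilcoxon_signed_rank(pre, post)
        b = wilcoxon_signed_rank(post, pre)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_exact_equals_enumeration_oracle(self, seed, alternative):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        pre = rng.integers(0, 8, size=n).astype(float)
        post = pre + rng.integers(-3, 4, size=n)
        if np.all(post == pre):
            post[0] += 1
        res = wilcoxon_signed_rank(pre, post, mode="exact", alternative=alternative)
        assert res.p == pytest.approx(
            enumeration_oracle(post - pre, alternative=alternative)
        )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = 10
            d = rng.permutation(np.arange(1, n + 1)) * rng.choice([-1, 1], size=n)
            pre = np.zeros(n)
            res = wilcoxon_signed_rank(pre, d, mode="exact")
            ref = scipy_wilcoxon(d, method="exact")
            assert res.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.8, 1, size=40)
        res = wilcoxon_signed_rank(pre, post)
        assert res.method == "normal"
        ref = scipy_wilcoxon(
            post - pre, method="approx", correction=False, alternative="two-sided"
        )
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_bad_arguments(self):
        with pytest.raises(ContractViolation):
            wilcoxon_signed_rank([], [])
        with pytest.raises(UsageError):
            wilcoxon_signed_rank([1], [2], zero_policy="ignore")
        with pytest.raises(UsageError):
            wilcoxon_signed_rank([1], [2], alternative="sideways")


# ---------------------------------------------------------------------
# internal consistency
# ---------------------------------------------------------------------


class TestConsistency:
    def test_identical_items_alpha_one(self):
        col = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        m = np.column_stack([col, col, col])
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_small_matrix_matches_hand_formula(self):
        m = np.array(
            [[1.0, 2.0, 3.0],
             [2.0, 4.0, 5.0],
             [3.0, 3.0, 4.0],
             [4.0, 5.0, 6.0]]
        )
        k = 3
        item_vars = m.var(axis=0, ddof=1).sum()
        total_var = m.sum(axis=1).var(ddof=1)
        expected = k / (k - 1) * (1 - item_vars / total_var)
        assert cronbach_alpha(m) == pytest.approx(expected)
        assert cronbach_alpha(m) <= 1.0

    def test_kr20_equals_alpha_on_binary(self):
        rng = np.random.default_rng(4)
        m = (rng.random((12, 6)) < 0.6).astype(float)
        if np.var(m.sum(axis=1), ddof=1) == 0:
            m[0, 0] = 1 - m[0, 0]
        assert kr20(m) == pytest.approx(cronbach_alpha(m))

    def test_kr20_requires_binary(self):
        with pytest.raises(ContractViolation):
            kr20(np.array([[0, 2], [1, 0]]))

    def test_zero_variance_flagged(self):
        m = np.ones((5, 3))
        with pytest.raises(ContractViolation):
            cronbach_alpha(m)

    def test_pairwise_missing_handled(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(20, 4))
        m_missing = m.copy()
        m_missing[0, 1] = np.nan
        a = cronbach_alpha(pd.DataFrame(m_missing))
        assert np.isfinite(a) and a <= 1.0


# ---------------------------------------------------------------------
# pre/post driver
# ---------------------------------------------------------------------


class TestComparePrePost:
    def test_listwise_pairing_and_output(self, pak_spec):
        sheets = []
        for r in ("a", "b", "c"):
            for tp in ("pre", "post"):
                answers = {
                    i.id: (i.correct if (tp == "post" or r == "a") else 6)
                    for i in pak_spec.items
                }
                sheets.append(ResponseSheet(r, pak_spec.name, answers, timepoint=tp))
        # one unpaired respondent must be excluded
        sheets.append(ResponseSheet("d", pak_spec.name,
                                    {i.id: 6 for i in pak_spec.items}, timepoint="pre"))
        out = compare_pre_post(sheets, pak_spec)
        assert out["n_pairs"] == 3
        assert out["excluded_respondents"] == ["d"]
        assert out["post"]["median"] == 100.0
        assert 0.0 <= out["wilcoxon"]["p"] <= 1.0
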