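"""Model assembly, discriminant algebra, risk stratification and ROC/AUC."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ladspectra as ls
from ladspectra.base import (
    POSITIVE_LABEL as POS, NEGATIVE_LABEL as NEG,
    SIGN_POSITIVE, SIGN_NEGATIVE, UNCLASSIFIED,
)
from ladspectra.patterns import Literal, GE, LT, pattern_stats
from ladspectra.model import exhaustive_sign_cover_size, DiscriminantResult

from conftest import make_matrix


def _perfect_model():
    m = make_matrix([[2.0], [2.5], [0.5], [1.0]], [POS, POS, NEG, NEG])
    pos = pattern_stats((Literal(0, 1.5, GE),), SIGN_POSITIVE, m)
    neg = pattern_stats((Literal(0, 1.5, LT),), SIGN_NEGATIVE, m)
    return m, pos, neg


class TestSelectModel:
    def test_single_pattern_per_sign_suffices(self):
        m, pos, neg = _perfect_model()
        model = ls.select_model([pos, neg], m)
        assert model.positive_patterns == [pos]
        assert model.negative_patterns == [neg]

    def test_engineered_two_pattern_cover_matches_oracle(self):
        # positives split into two clusters needing two patterns
        m = make_matrix([[5, 0], [0, 5], [1, 1], [0.5, 0.5]],
                        [POS, POS, NEG, NEG])
        p1 = pattern_stats((Literal(0, 3.0, GE),), SIGN_POSITIVE, m)
        p2 = pattern_stats((Literal(1, 3.0, GE),), SIGN_POSITIVE, m)
        n1 = pattern_stats((Literal(0, 3.0, LT), Literal(1, 3.0, LT)),
                           SIGN_NEGATIVE, m)
        model = ls.select_model([p1, p2, n1], m)
        assert len(model.positive_patterns) == 2
        assert exhaustive_sign_cover_size([p1, p2], {0, 1}) == 2

    def test_uncoverable_patient_named(self):
        m = make_matrix([[5.0], [0.1], [1.0]], [POS, POS, NEG],
                        ids=["pa", "pb", "nc"])
        p1 = pattern_stats((Literal(0, 3.0, GE),), SIGN_POSITIVE, m)
        n1 = pattern_stats((Literal(0, 2.0, LT),), SIGN_NEGATIVE, m)
        # pb (value 0.1) is not covered by p1, and no other positive exists
        with pytest.raises(ls.InfeasibleError, match="pb"):
            ls.select_model([p1, n1], m)

    def test_recovery_model_is_small_and_covers_training(self, recovery_cohort):
        m = recovery_cohort["matrix"]
        fitted = ls.fit_lad_pipeline(m)
        model = fitted.model
        assert 1 <= model.P <= 8 and 1 <= model.N <= 8
        labels = m.label_array()
        pos_cov = set().union(*[p.covered for p in model.positive_patterns])
        neg_cov = set().union(*[p.covered for p in model.negative_patterns])
        assert set(np.flatnonzero(labels == POS)) <= pos_cov
        assert set(np.flatnonzero(labels == NEG)) <= neg_cov

    def test_model_requires_both_signs(self):
        m, pos, neg = _perfect_model()
        with pytest.raises(ls.ConfigError):
            ls.LADModel(positive_patterns=[pos], negative_patterns=[])


class TestDiscriminant:
    def test_extremes(self):
        m, pos, neg = _perfect_model()
        model = ls.LADModel([pos], [neg])
        hi = ls.discriminant(model, np.array([2.0]))
        lo = ls.discriminant(model, np.array([0.5]))
        assert hi.delta == 1.0 and hi.risk == 1.0 and hi.predicted == POS
        assert lo.delta == -1.0 and lo.risk == 0.0 and lo.predicted == NEG

    def test_forced_arithmetic_p2_of_3_n1_of_4(self):
        # delta = 2/3 - 1/4 = 5/12, risk = 17/24, predicted positive
        r = DiscriminantResult(p=2, n=1, P=3, N=4,
                               delta_fraction=Fraction(2, 3) - Fraction(1, 4),
                               predicted=POS)
        assert r.delta_fraction == Fraction(5, 12)
        assert r.delta == pytest.approx(5 / 12)
        assert r.risk == pytest.approx(17 / 24)

    @given(st.integers(1, 6), st.integers(1, 6), st.data())
    @settings(max_examples=120, deadline=None)
    def test_bounds_sign_rule_and_affine_risk(self, P, N, data):
        p = data.draw(st.integers(0, P))
        n = data.draw(st.integers(0, N))
        delta = Fraction(p, P) - Fraction(n, N)
        pred = POS if delta > 0 else NEG if delta < 0 else UNCLASSIFIED
        r = DiscriminantResult(p=p, n=n, P=P, N=N, delta_fraction=delta,
                               predicted=pred)
        assert -1 <= r.delta <= 1
        assert 0 <= r.risk <= 1
        assert r.risk == pytest.approx((r.delta + 1) / 2)
        if r.delta > 0:
            assert r.predicted == POS
        elif r.delta < 0:
            assert r.predicted == NEG
        else:
            assert r.predicted == UNCLASSIFIED

    def test_unclassified_surfaced_on_real_model(self):
        m, pos, neg = _perfect_model()
        both = ls.LADModel([pos], [neg])
        # a vector covered by neither side (impossible here since the two
        # literals partition the line) -> craft a two-pattern model instead
        m2 = make_matrix([[2.0, 2.0], [0.5, 0.5]], [POS, NEG])
        p = pattern_stats((Literal(0, 1.0, GE),), SIGN_POSITIVE, m2)
        n = pattern_stats((Literal(1, 1.0, LT),), SIGN_NEGATIVE, m2)
        model = ls.LADModel([p], [n])
        res = ls.discriminant(model, np.array([2.0, 0.5]))  # covered by both
        assert res.delta == 0 and res.predicted == UNCLASSIFIED
        assert both.P == 1  # silence unused warning


class TestRiskGroups:
    def _results(self, risks):
        out = []
        for r in risks:
            delta = Fraction(r).limit_denominator(10**6) * 2 - 1
            pred = POS if delta > 0 else NEG if delta < 0 else UNCLASSIFIED
            out.append(DiscriminantResult(p=0, n=0, P=1, N=1,
                                          delta_fraction=delta, predicted=pred))
        return out

    def test_quintiles_of_116_are_23_23_23_23_24(self):
        rng = np.random.default_rng(0)
        risks = rng.random(116)
        res = self._results(risks)
        labels = [POS if r > 0.5 else NEG for r in risks]
        ids = [f"p{i:03d}" for i in range(116)]
        table = ls.risk_groups(res, labels, ids, g=5)
        assert table.table["n"].tolist() == [23, 23, 23, 23, 24]
        assert table.table["n"].sum() == 116
        assert table.table["mean_risk"].is_monotonic_increasing

    def test_identical_scores_tie_break_by_patient_id(self):
        res = self._results([0.5] * 6)
        labels = [POS, NEG, POS, NEG, POS, NEG]
        ids = ["f", "e", "d", "c", "b", "a"]
        table = ls.risk_groups(res, labels, ids, g=3)
        by_group = table.assignments.sort_values("group")["patient_id"].tolist()
        assert by_group == ["a", "b", "c", "d", "e", "f"]
        assert set(table.table["pct_positive"]) <= {0.0, 50.0, 100.0}

    def test_separated_cohort_bottom_0_top_100(self, recovery_cohort):
        m = recovery_cohort["matrix"]
        fitted = ls.fit_lad_pipeline(m)
        res = ls.predict_matrix(fitted.model, m)
        table = ls.risk_groups(res, m.labels, m.patient_ids, g=5)
        assert table.table.iloc[0]["pct_positive"] == 0.0
        assert table.table.iloc[-1]["pct_positive"] == 100.0


class TestROC:
    def test_perfect_and_constant_scores(self):
        labels = [POS] * 5 + [NEG] * 5
        assert ls.roc_auc(np.r_[np.ones(5), np.zeros(5)], labels).auc == 1.0
        assert ls.roc_auc(np.ones(10), labels).auc == 0.5

    def test_matches_pairwise_count_oracle_and_sklearn(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 10, 30).astype(float)  # force ties
        labels = [POS if rng.random() < 0.5 else NEG for _ in range(30)]
        labels[0], labels[1] = POS, NEG
        res = ls.roc_auc(scores, labels)
        pos = [s for s, l in zip(scores, labels) if l == POS]
        neg = [s for s, l in zip(scores, labels) if l == NEG]
        brute = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                         for a in pos for b in neg])
        assert res.auc == pytest.approx(brute, abs=1e-12)
        from sklearn.metrics import roc_auc_score
        assert res.auc == pytest.approx(
            roc_auc_score([l == POS for l in labels], scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = [POS] * 20 + [NEG] * 20
        a = ls.roc_auc(scores, labels).auc
        b = ls.roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ls.LADError, match="both classes"):
            ls.roc_auc([1.0, 2.0], [POS, POS])

    def test_hanley_mcneil_ci_brackets_auc_and_bootstrap_close(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        labels = [POS] * 30 + [NEG] * 30
        hm = ls.roc_auc(scores, labels)
        assert hm.ci_low <= hm.auc <= hm.ci_high
        bs = ls.roc_auc(scores, labels, ci="bootstrap", seed=0)
        assert bs.auc == hm.auc
        assert abs(bs.ci_low - hm.ci_low) < 0.1
        assert abs(bs.ci_high - hm.ci_high) < 0.1
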