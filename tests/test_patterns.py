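"""Pattern coverage, prevalence/homogeneity statistics, exhaustive
enumeration vs a brute-force oracle, and the degree-1 feature screen."""

from itertools import combinations, product

import numpy as np
import pytest

import ladspectra as ls
from ladspectra.base import (
    POSITIVE_LABEL as POS, NEGATIVE_LABEL as NEG,
    SIGN_POSITIVE, SIGN_NEGATIVE,
)
from ladspectra.patterns import Literal, GE, LT, pattern_stats

from conftest import make_matrix, planted_bin_centers


def _p1_matrix():
    # two features standing for the bins at m/z 9,940 and 11,274
    return make_matrix(
        [[0.50, 0.06], [0.60, 0.06], [0.50, 0.02], [0.70, 0.01]],
        [POS, NEG, NEG, NEG],
        centers=[9940.0, 11274.0],
    )


P1 = (Literal(0, 0.575, LT), Literal(1, 0.055, GE))


class TestCoverage:
    def test_p1_covers_matching_patient(self):
        m = _p1_matrix()
        p = pattern_stats(P1, SIGN_POSITIVE, m)
        assert p is not None
        assert ls.pattern_covers(p, np.array([0.50, 0.06]))

    def test_p1_rejects_on_first_literal(self):
        m = _p1_matrix()
        p = pattern_stats(P1, SIGN_POSITIVE, m)
        assert not ls.pattern_covers(p, np.array([0.60, 0.06]))

    def test_degree_zero_rejected(self):
        with pytest.raises(ls.ConfigError, match="degree"):
            ls.Pattern(sign=SIGN_POSITIVE, literals=(), prevalence=1.0,
                       homogeneity=1.0, covered=frozenset({0}),
                       own_covered=1, other_covered=0, own_total=1)

    def test_duplicate_literal_rejected(self):
        with pytest.raises(ls.ConfigError):
            ls.Pattern(sign=SIGN_POSITIVE,
                       literals=(Literal(0, 0.5, GE), Literal(0, 0.5, LT)),
                       prevalence=1.0, homogeneity=1.0, covered=frozenset({0}),
                       own_covered=1, other_covered=0, own_total=1)

    def test_missing_feature_raises(self):
        m = _p1_matrix()
        p = pattern_stats(P1, SIGN_POSITIVE, m)
        with pytest.raises(ls.LADError, match="missing feature"):
            ls.pattern_covers(p, np.array([0.5]))


class TestStats:
    def test_counting_eight_of_ten_and_two_others(self):
        values = np.r_[np.linspace(1, 2, 8), [0.1, 0.2],   # 8 pos high, 2 pos low
                       [1.5, 1.6], np.linspace(0.1, 0.5, 8)]  # 2 neg high, 8 neg low
        m = make_matrix(values[:, None], [POS] * 10 + [NEG] * 10)
        p = pattern_stats((Literal(0, 0.75, GE),), SIGN_POSITIVE, m)
        assert p.prevalence == pytest.approx(0.8)
        assert p.homogeneity == pytest.approx(0.8)
        assert (p.own_covered, p.other_covered, p.own_total) == (8, 2, 10)

    def test_perfect_pattern(self):
        m = make_matrix([[2.0], [2.5], [1.0], [0.5]], [POS, POS, NEG, NEG])
        p = pattern_stats((Literal(0, 1.5, GE),), SIGN_POSITIVE, m)
        assert p.prevalence == 1.0 and p.homogeneity == 1.0

    def test_zero_own_coverage_is_rejection_not_error(self):
        m = make_matrix([[1.0], [2.0]], [POS, NEG])
        assert pattern_stats((Literal(0, 1.5, GE),), SIGN_POSITIVE, m) is None

    def test_toy_matrix_matches_hand_count(self):
        m = make_matrix([[1, 9], [2, 8], [3, 1], [4, 2]], [POS, POS, NEG, NEG])
        p = pattern_stats((Literal(0, 2.5, LT), Literal(1, 5.0, GE)),
                          SIGN_POSITIVE, m)
        covered = {i for i in range(4)
                   if m.values[i, 0] < 2.5 and m.values[i, 1] >= 5.0}
        assert p.covered == frozenset(covered) == {0, 1}

    def test_stat_identities_exact_counts(self, cv_cohort):
        m = cv_cohort["matrix"]
        cuts = ls.compute_cutpoints(m)
        f = next(iter(cuts.cutpoints))
        c = cuts.cutpoints[f][len(cuts.cutpoints[f]) // 2]
        for sign in (SIGN_POSITIVE, SIGN_NEGATIVE):
            p = pattern_stats((Literal(f, c, GE),), sign, m)
            if p is None:
                continue
            assert p.homogeneity * len(p.covered) == pytest.approx(p.own_covered)
            assert p.prevalence * p.own_total == pytest.approx(p.own_covered)


def _brute_force_enumerate(m, cuts, sign, max_degree, min_hom, min_prev):
    feats = sorted(cuts.cutpoints)
    lits = {f: [Literal(f, c, d) for c in cuts.cutpoints[f] for d in (GE, LT)]
            for f in feats}
    out = set()
    for degree in range(1, max_degree + 1):
        for combo in combinations(feats, degree):
            for ls_ in product(*(lits[f] for f in combo)):
                p = pattern_stats(ls_, sign, m)
                if p and p.homogeneity >= min_hom and p.prevalence >= min_prev:
                    out.add((p.sign, p.literals))
    return out


class TestEnumeration:
    def test_impossible_thresholds_give_empty(self):
        m = make_matrix([[1.0], [2.0], [1.5], [2.5]], [POS, POS, NEG, NEG])
        cuts = ls.compute_cutpoints(m)
        out = ls.enumerate_patterns(m, cuts, sign=SIGN_POSITIVE, max_degree=2,
                                    min_homogeneity=1.0, min_prevalence=1.0)
        assert out == []

    def test_perfect_planted_feature_yields_perfect_pattern(self):
        m = make_matrix([[5.0, 1.0], [6.0, 2.0], [1.0, 1.5], [2.0, 2.5]],
                        [POS, POS, NEG, NEG])
        cuts = ls.compute_cutpoints(m)
        out = ls.enumerate_patterns(m, cuts, sign=SIGN_POSITIVE, max_degree=1,
                                    min_homogeneity=1.0, min_prevalence=1.0)
        assert any(p.prevalence == 1.0 and p.homogeneity == 1.0 for p in out)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, f = int(rng.integers(6, 13)), int(rng.integers(2, 5))
        m = make_matrix(rng.integers(0, 5, size=(n, f)).astype(float),
                        [POS if rng.random() < 0.5 else NEG for _ in range(n)])
        if POS not in m.labels or NEG not in m.labels:
            m.labels[0], m.labels[1] = POS, NEG
        cuts = ls.compute_cutpoints(m)
        for sign in (SIGN_POSITIVE, SIGN_NEGATIVE):
            got = ls.enumerate_patterns(m, cuts, sign=sign, max_degree=2,
                                        min_homogeneity=0.6, min_prevalence=0.3)
            expect = _brute_force_enumerate(m, cuts, sign, 2, 0.6, 0.3)
            assert {(p.sign, p.literals) for p in got} == expect

    def test_threshold_monotonicity_and_degree_nesting(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.integers(0, 4, size=(10, 3)).astype(float),
                        [POS] * 5 + [NEG] * 5)
        cuts = ls.compute_cutpoints(m)
        loose = ls.enumerate_patterns(m, cuts, sign=SIGN_POSITIVE, max_degree=2,
                                      min_homogeneity=0.5, min_prevalence=0.2)
        tight = ls.enumerate_patterns(m, cuts, sign=SIGN_POSITIVE, max_degree=2,
                                      min_homogeneity=0.8, min_prevalence=0.4)
        assert {(p.sign, p.literals) for p in tight} <= \
               {(p.sign, p.literals) for p in loose}
        d1 = ls.enumerate_patterns(m, cuts, sign=SIGN_POSITIVE, max_degree=1,
                                   min_homogeneity=0.5, min_prevalence=0.2)
        assert {(p.sign, p.literals) for p in d1} == \
               {(p.sign, p.literals) for p in loose if p.degree == 1}


class TestDegree1Filter:
    def test_vacuous_thresholds_retain_everything_with_cutpoints(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.integers(0, 4, size=(8, 4)).astype(float),
                        [POS] * 4 + [NEG] * 4)
        cuts = ls.compute_cutpoints(m)
        retained = ls.degree1_feature_filter(m, cuts, 0.0, 0.0)
        assert retained == cuts.features_with_cutpoints()

    def test_recovery_cohort_retains_all_planted_masses(self, recovery_cohort):
        m = recovery_cohort["matrix"]
        cuts = ls.compute_cutpoints(m)
        retained = ls.degree1_feature_filter(m, cuts)
        retained_mz = {float(m.bin_centers[f]) for f in retained}
        assert retained_mz >= set(planted_bin_centers(recovery_cohort["config"]))

    def test_pure_noise_cohort_retains_almost_nothing(self):
        cfg = ls.cv_scale_config(seed=8, planted_masses=())
        records = ls.generate_cohort(cfg)
        spec = ls.BinningSpec(cfg.mz_range[0], cfg.mz_range[1] - 2.0, 2.0)
        m, _ = ls.build_feature_matrix(records, spec, standard_mz=cfg.standard_mz)
        retained = ls.degree1_feature_filter(m, ls.compute_cutpoints(m))
        assert len(retained) < 0.01 * m.n_features

    def test_vectorized_filter_agrees_with_enumeration(self):
        """The searchsorted fast path must match the definitional route
        through degree-1 pattern enumeration."""
        rng = np.random.default_rng(17)
        m = make_matrix(rng.normal(2, 1, size=(20, 6)).clip(0),
                        [POS] * 9 + [NEG] * 11)
        cuts = ls.compute_cutpoints(m)
        fast = set(ls.degree1_feature_filter(m, cuts, 0.6, 0.5))
        slow = set()
        for sign in (SIGN_POSITIVE, SIGN_NEGATIVE):
            for p in ls.enumerate_patterns(m, cuts, sign=sign, max_degree=1,
                                           min_homogeneity=0.6, min_prevalence=0.5):
                slow.add(p.literals[0].feature)
        assert fast == slow
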