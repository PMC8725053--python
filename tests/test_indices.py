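import itertools

import numpy as np
import pytest
from scipy import stats

from carescreen import (
    ResponseMatrix,
    ScaleDesign,
    ValidationError,
    recode_reversed,
)
from carescreen.indices import (
    FlagRule,
    TwoSidedFlags,
    antonym_scores,
    apply_flag_rule,
    evenodd_scores,
    irv_scores,
    longstring_scores,
    mahalanobis_scores,
)


class TestMahalanobis:
    def test_center_point_has_zero_distance(self):
        vals = np.array([[1, 2], [5, 2], [3, 1], [3, 3], [3, 2]])
        # row 4 sits at the sample centroid (3, 2)
        d2 = mahalanobis_scores(ResponseMatrix(vals)).scores
        assert d2[4] == pytest.approx(0.0, abs=1e-10)

    def test_matches_explicit_inverse_on_2x2(self):
        vals = np.array([[1, 2], [3, 5], [5, 3]])
        X = vals.astype(float)
        xbar = X.mean(0)
        S = np.cov(X.T, ddof=1)
        Sinv = np.linalg.inv(S)
        expected = np.array([(x - xbar) @ Sinv @ (x - xbar) for x in X])
        d2 = mahalanobis_scores(ResponseMatrix(vals)).scores
        assert np.allclose(d2, expected, atol=1e-10)

    def test_mean_identity(self, rng):
        # algebraic identity for (n-1)-denominator covariance
        n, J = 120, 20
        X = ResponseMatrix(rng.integers(1, 6, size=(n, J)))
        d2 = mahalanobis_scores(X).scores
        assert d2.mean() == pytest.approx(J * (n - 1) / n, abs=1e-9)

    def test_singular_covariance_needs_ridge(self, rng):
        vals = rng.integers(1, 6, size=(10, 20))   # n < J: singular S
        with pytest.raises(ValidationError, match="singular"):
            mahalanobis_scores(ResponseMatrix(vals))
        d2 = mahalanobis_scores(ResponseMatrix(vals), ridge=0.1).scores
        assert np.isfinite(d2).all()

    def test_random_rows_rank_monotone_under_more_injection(self, gen_spec, design, rng):
        # injected uniform rows never lose percentile rank when more are added
        from carescreen.simulate import sample_regular

        reg = sample_regular(150, gen_spec, seed=11).values
        rand = rng.integers(1, 6, size=(30, 60))

        def mean_rank(k):
            X = ResponseMatrix(np.vstack([reg, rand[:k]]))
            d2 = mahalanobis_scores(recode_reversed(X, design)).scores
            ranks = stats.rankdata(d2) / len(d2)
            return ranks[150:].mean()

        assert mean_rank(30) > 0.9
        assert abs(mean_rank(10) - mean_rank(30)) < 0.1


class TestAntonyms:
    @staticmethod
    def _mirrored_sample(rng, n_struct=200, n_rand=200):
        first = rng.integers(1, 6, size=(n_struct, 3))
        struct = np.hstack([first, 6 - first])
        rand = rng.integers(1, 6, size=(n_rand, 6))
        return np.vstack([struct, rand])

    def test_perfectly_mirrored_respondent_scores_minus_one(self, rng):
        vals = self._mirrored_sample(rng)
        vals[0] = [1, 3, 5, 5, 3, 1]    # exact mirror with variance
        s = antonym_scores(ResponseMatrix(vals))
        assert s.scores[0] == pytest.approx(-1.0)

    def test_random_respondents_score_near_zero_on_average(self, rng):
        vals = self._mirrored_sample(rng)
        s = antonym_scores(ResponseMatrix(vals))
        rand_scores = s.scores[200:]
        assert abs(np.nanmean(rand_scores)) < 0.1

    def test_too_strict_criterion_errors(self, rng):
        vals = rng.integers(1, 6, size=(50, 10))
        with pytest.raises(ValidationError, match="laxer"):
            antonym_scores(ResponseMatrix(vals), r_crit=-0.99)


class TestEvenOdd:
    def test_perfectly_consistent_respondent(self, design, rng):
        vals = rng.integers(1, 6, size=(40, 60))
        half_means = [1, 2, 3, 4, 5, 2]    # varies across constructs
        for c, m in zip(design.construct_ids, half_means):
            items = design.items_of(c)
            raw = np.where(design.reversed_items[items], 6 - m, m)
            vals[0, items] = raw
        s = evenodd_scores(ResponseMatrix(vals), design)
        assert s.scores[0] == pytest.approx(1.0)

    def test_constant_responding_is_undefined(self, design, rng):
        vals = rng.integers(1, 6, size=(10, 60))
        vals[3] = 3
        s = evenodd_scores(ResponseMatrix(vals), design)
        assert np.isnan(s.scores[3])
        assert s.n_undefined >= 1

    def test_regular_beat_random_on_average(self, design, gen_spec, rng):
        from carescreen.simulate import sample_regular

        reg = sample_regular(300, gen_spec, seed=21).values
        rand = rng.integers(1, 6, size=(300, 60))
        s_reg = evenodd_scores(ResponseMatrix(reg), design).scores
        s_rand = evenodd_scores(ResponseMatrix(rand), design).scores
        assert np.nanmean(s_reg) > np.nanmean(s_rand)


class TestLongstring:
    def test_definition_examples(self):
        row1 = [3, 3, 3, 3, 3, 3] + [1, 2] * 27
        row2 = [1, 2] * 30
        s = longstring_scores(ResponseMatrix(np.array([row1, row2])))
        assert s.scores.tolist() == [6.0, 1.0]

    def test_matches_brute_force_oracle(self, rng):
        def oracle(row):
            return max(len(list(g)) for _, g in itertools.groupby(row))

        X = rng.integers(1, 6, size=(1000, 60))
        s = longstring_scores(ResponseMatrix(X))
        expected = [oracle(row) for row in X]
        assert s.scores.tolist() == expected

    def test_mean_run_reported(self):
        s = longstring_scores(ResponseMatrix(np.array([[1, 1, 2, 2, 2, 3]])))
        assert s.extras["mean_run"][0] == pytest.approx(2.0)


class TestIRV:
    def test_closed_forms(self):
        const = np.full((1, 60), 3)
        alt = np.tile([1, 5], 30)[None, :]
        s = irv_scores(ResponseMatrix(np.vstack([const, alt])))
        assert s.scores[0] == 0.0
        assert s.scores[1] == pytest.approx(2 * np.sqrt(60 / 59))

    def test_uniform_rows_mean_sqrt2(self, rng):
        X = rng.integers(1, 6, size=(3000, 60))
        s = irv_scores(ResponseMatrix(X))
        assert s.scores.mean() == pytest.approx(np.sqrt(2), abs=0.02)

    def test_matches_numpy_oracle(self, rng):
        X = rng.integers(1, 6, size=(200, 60))
        s = irv_scores(ResponseMatrix(X))
        assert np.allclose(s.scores, X.std(axis=1, ddof=1))


class TestFlagRules:
    def test_chi_square_cutoff_at_df60(self):
        # chi-square table value for the .95 quantile at 60 df
        from carescreen.indices import IndexScores

        scores = IndexScores("mahalanobis", np.array([80.0, 79.0]), "high")
        rule = FlagRule("chi_square", {"alpha": 0.05, "df": 60})
        cutoff = stats.chi2.ppf(0.95, 60)
        assert cutoff == pytest.approx(79.0819, abs=1e-3)
        flags = apply_flag_rule(scores, rule)
        assert flags.flags.tolist() == [True, False]

    def test_two_sided_percentiles_flag_about_ten_percent(self, rng):
        from carescreen.indices import IndexScores

        scores = IndexScores("irv", rng.standard_normal(2000), "two-sided")
        two = apply_flag_rule(scores, FlagRule("two_sided_percentile",
                                               {"lo": 5, "hi": 95}))
        assert isinstance(two, TwoSidedFlags)
        frac = (two.low.flags | two.high.flags).mean()
        assert abs(frac - 0.10) < 0.02

    def test_empty_scores_rejected(self):
        from carescreen.indices import IndexScores

        scores = IndexScores("irv", np.array([]), "two-sided")
        with pytest.raises(ValidationError):
            apply_flag_rule(scores, FlagRule("percentile", {"q": 95}))

    def test_nan_never_flagged(self):
        from carescreen.indices import IndexScores

        scores = IndexScores("evenodd", np.array([np.nan, -1.0, 0.9]), "low")
        flags = apply_flag_rule(scores, FlagRule("absolute", {"threshold": 0.3}))
        assert flags.flags.tolist() == [False, True, False]
        assert flags.n_undefined == 1


def test_flagging_is_permutation_equivariant(design, gen_spec, rng):
    from carescreen.simulate import sample_regular

    reg = sample_regular(100, gen_spec, seed=31).values
    rand = rng.integers(1, 6, size=(20, 60))
    vals = np.vstack([reg, rand])
    perm = rng.permutation(120)

    for scorer in (lambda V: longstring_scores(ResponseMatrix(V)).scores,
                   lambda V: irv_scores(ResponseMatrix(V)).scores,
                   lambda V: mahalanobis_scores(ResponseMatrix(V)).scores):
        direct = scorer(vals)
        permuted = scorer(vals[perm])
        assert np.allclose(direct[perm], permuted)
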