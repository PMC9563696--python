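"""Match play, the team Bradley-Terry likelihood, and the ML ranking fit.

Oracles used here are independent of the implementation path: a plain
arithmetic evaluation of the likelihood, the classic minorization (MM)
algorithm for single-feature ledgers, iterative grid refinement over the
sum-zero simplex, and finite-difference Hessians for the delta-method
covariance.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teamrank.data_model import FIT_FAILURE, FeatureSet, ModelAdapter
from teamrank.ranking import (
    MatchLedger,
    MatchRecord,
    fit_ranking,
    generate_matches,
    negative_log_likelihood,
    play_match,
    select_top,
    set_strength_ci,
)

from conftest import (
    constant_adapter,
    failing_adapter,
    oracle_adapter,
    random_singles_ledger,
    single_match_ledger,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def naive_nll(scores: dict[str, float], ledger: MatchLedger, ridge: float = 0.0) -> float:
    """Direct arithmetic evaluation of the match likelihood (no log-sum-exp)."""
    total = 0.0
    for m in ledger.matches:
        tp = sum(scores[f] for f in m.team_plus)
        tm = sum(scores[f] for f in m.team_minus)
        p_plus = math.exp(tp) / (math.exp(tp) + math.exp(tm))
        total -= m.wins_plus * math.log(p_plus) + m.wins_minus * math.log(1.0 - p_plus)
    return total + ridge * sum(v * v for v in scores.values())


def mm_bradley_terry(ledger: MatchLedger, n_iter: int = 2000) -> np.ndarray:
    """Classic minorization updates for single-feature (t=1) ledgers.

    pi_i <- W_i / sum_j N_ij / (pi_i + pi_j); returns centered log-strengths.
    """
    names = list(ledger.feature_universe)
    p = len(names)
    wins = np.zeros(p)
    games = np.zeros((p, p))
    idx = {n: i for i, n in enumerate(names)}
    for m in ledger.matches:
        (i,) = (idx[f] for f in m.team_plus)
        (j,) = (idx[f] for f in m.team_minus)
        wins[i] += m.wins_plus
        wins[j] += m.wins_minus
        games[i, j] += m.wins_plus + m.wins_minus
        games[j, i] += m.wins_plus + m.wins_minus
    pi = np.ones(p)
    for _ in range(n_iter):
        denom = np.array(
            [sum(games[i, j] / (pi[i] + pi[j]) for j in range(p) if j != i) for i in range(p)]
        )
        pi = wins / denom
        pi = pi / pi.sum()
    v = np.log(pi)
    return v - v.mean()


def grid_refine_optimum(ledger: MatchLedger, passes: int = 12) -> np.ndarray:
    """Dense grid search over the sum-zero simplex, iteratively refined."""
    names = list(ledger.feature_universe)
    k = len(names) - 1  # free coordinates; last is -sum
    center = np.zeros(k)
    half = 4.0
    for _ in range(passes):
        offsets = np.linspace(-half, half, 9)
        best_val, best_free = np.inf, center
        for combo in np.stack(np.meshgrid(*[offsets] * k), axis=-1).reshape(-1, k):
            free = center + combo
            full = np.append(free, -free.sum())
            val = naive_nll(dict(zip(names, full)), ledger)
            if val < best_val:
                best_val, best_free = val, free
        center = best_free
        half *= 0.35
    full = np.append(center, -center.sum())
    return full - full.mean()


def fd_hessian(func, x0: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    p = len(x0)
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            x = x0.copy()

            def f(di, dj):
                y = x0.copy()
                y[i] += di
                y[j] += dj
                return func(y)

            H[i, j] = (f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h * h)
    return H


def is_strongly_connected(ledger: MatchLedger) -> bool:
    """Ford's condition proxy: every feature has at least one win and one loss."""
    gains = {n: 0.0 for n in ledger.feature_universe}
    losses = {n: 0.0 for n in ledger.feature_universe}
    for m in ledger.matches:
        for f in m.team_plus:
            gains[f] += m.wins_plus
            losses[f] += m.wins_minus
        for f in m.team_minus:
            gains[f] += m.wins_minus
            losses[f] += m.wins_plus
    return all(gains[n] > 0 and losses[n] > 0 for n in ledger.feature_universe)


# ---------------------------------------------------------------------------
# match play
# ---------------------------------------------------------------------------


class TestPlayMatch:
    def test_constant_metric_splits_wins_evenly(self, regression_dataset):
        rec = play_match(
            FeatureSet(["x1", "x2"]),
            FeatureSet(["x3", "x4"]),
            regression_dataset,
            constant_adapter(),
            rounds=10,
            rng=np.random.default_rng(0),
        )
        assert rec.wins_plus == rec.wins_minus == 5.0

    def test_oracle_team_wins_every_round(self, regression_dataset):
        rec = play_match(
            FeatureSet(["x1", "x2"]),
            FeatureSet(["x3", "x4"]),
            regression_dataset,
            oracle_adapter({"x1"}),
            rounds=20,
            rng=np.random.default_rng(1),
        )
        assert rec.wins_plus == 20.0 and rec.wins_minus == 0.0

    def test_failing_opponent_loses_every_round(self, regression_dataset):
        adapter = failing_adapter({frozenset({"x3", "x4"})})
        rec = play_match(
            FeatureSet(["x1", "x2"]),
            FeatureSet(["x3", "x4"]),
            regression_dataset,
            adapter,
            rounds=7,
            rng=np.random.default_rng(2),
        )
        assert rec.wins_plus == rec.rounds_played == 7

    def test_both_fail_round_discarded(self, regression_dataset):
        adapter = failing_adapter({frozenset({"x1", "x2"}), frozenset({"x3", "x4"})})
        rec = play_match(
            FeatureSet(["x1", "x2"]),
            FeatureSet(["x3", "x4"]),
            regression_dataset,
            adapter,
            rounds=5,
            rng=np.random.default_rng(3),
        )
        assert rec.wins_plus == rec.wins_minus == 0.0
        assert rec.rounds_played == 5

    def test_overlapping_teams_rejected(self, regression_dataset):
        with pytest.raises(ValueError, match="disjoint"):
            play_match(
                FeatureSet(["x1", "x2"]),
                FeatureSet(["x2", "x3"]),
                regression_dataset,
                constant_adapter(),
                rounds=2,
            )

    def test_raising_adapter_reported_with_team_identity(self, regression_dataset):
        def bad_fit(train, features):
            raise RuntimeError("boom")

        adapter = ModelAdapter(bad_fit, lambda h, v: 0.0, "maximize")
        with pytest.raises(RuntimeError, match="x1"):
            play_match(
                FeatureSet(["x1"]), FeatureSet(["x2"]), regression_dataset, adapter, rounds=2
            )


class TestGenerateMatches:
    def test_full_coverage_first_match(self, regression_dataset):
        ds = regression_dataset.restrict_features(FeatureSet(["x1", "x2", "x3", "x4"]))
        ledger = generate_matches(ds, constant_adapter(), team_size=2, rounds=2, min_evals=1)
        assert ledger.n_matches == 1
        assert all(c >= 1 for c in ledger.eval_counts.values())

    def test_stopping_rule_min_evals(self, regression_dataset):
        ledger = generate_matches(
            regression_dataset, constant_adapter(), team_size=2, rounds=2, min_evals=3, seed=5
        )
        assert min(ledger.eval_counts.values()) >= 3
        assert ledger.eval_counts == ledger.recount()

    def test_fixed_seed_reproducible(self, regression_dataset):
        a = generate_matches(regression_dataset, constant_adapter(), team_size=2, rounds=3, min_evals=2, seed=9)
        b = generate_matches(regression_dataset, constant_adapter(), team_size=2, rounds=3, min_evals=2, seed=9)
        assert a.matches == b.matches

    def test_max_matches_cap(self, regression_dataset):
        ledger = generate_matches(
            regression_dataset, constant_adapter(), team_size=2, rounds=1, min_evals=50, max_matches=4, seed=0
        )
        assert ledger.n_matches == 4

    def test_team_size_too_large(self, regression_dataset):
        with pytest.raises(ValueError, match="team_size"):
            generate_matches(regression_dataset, constant_adapter(), team_size=4, rounds=1, min_evals=1)

    def test_ledger_csv_roundtrip(self, regression_dataset, tmp_path):
        ledger = generate_matches(
            regression_dataset, constant_adapter(), team_size=2, rounds=4, min_evals=1, seed=3
        )
        path = tmp_path / "ledger.csv"
        ledger.to_csv(path)
        back = MatchLedger.from_csv(path, ledger.feature_universe)
        assert back.matches == ledger.matches


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestNegativeLogLikelihood:
    def test_zero_scores_single_even_match(self):
        ledger = single_match_ledger(1.0, 1.0)
        assert negative_log_likelihood([0.0, 0.0], ledger) == pytest.approx(2 * math.log(2))

    def test_zero_scores_equal_total_wins_log2(self):
        ledger = random_singles_ledger(5, 12, seed=1)
        value = negative_log_likelihood(np.zeros(5), ledger)
        assert value == pytest.approx(ledger.total_wins * math.log(2))

    def test_hand_computed_two_player_value(self):
        # v = (+log(3)/2, -log(3)/2): p+ = 3/4, so NLL = -(3 log 3/4 + log 1/4)
        ledger = single_match_ledger(3.0, 1.0)
        v = [math.log(3) / 2, -math.log(3) / 2]
        expected = -(3 * math.log(0.75) + math.log(0.25))
        assert negative_log_likelihood(v, ledger) == pytest.approx(expected)

    def test_matches_naive_arithmetic_oracle(self):
        ledger = random_singles_ledger(4, 10, seed=7)
        rng = np.random.default_rng(0)
        v = rng.normal(size=4)
        expected = naive_nll(dict(zip(ledger.feature_universe, v)), ledger, ridge=0.05)
        assert negative_log_likelihood(v, ledger, ridge=0.05) == pytest.approx(expected)

    def test_no_overflow_for_huge_score_sums(self):
        ledger = single_match_ledger(3.0, 1.0)
        value = negative_log_likelihood([700.0, -700.0], ledger)
        assert np.isfinite(value)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(-50, 50), seed=st.integers(0, 10**6))
    def test_shift_invariance(self, shift, seed):
        """Adding a constant to every score leaves the unpenalized NLL unchanged."""
        ledger = random_singles_ledger(4, 8, seed=seed % 100)
        v = np.random.default_rng(seed).normal(size=4)
        a = negative_log_likelihood(v, ledger)
        b = negative_log_likelihood(v + shift, ledger)
        assert a == pytest.approx(b, abs=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scores"):
            negative_log_likelihood([0.0], single_match_ledger())


# ---------------------------------------------------------------------------
# ranking fit
# ---------------------------------------------------------------------------


class TestFitRanking:
    def test_two_player_closed_form_log3(self):
        """n+=3, n-=1 on singles: the two-player MLE gives p = 3/4, dv = log 3."""
        est = fit_ranking(single_match_ledger(3.0, 1.0), ridge=0.0)
        diff = est.score_of("a") - est.score_of("b")
        assert diff == pytest.approx(math.log(3), abs=1e-6)
        assert est.converged

    def test_symmetric_ledger_all_zero(self):
        ledger = single_match_ledger(2.0, 2.0)
        est = fit_ranking(ledger)
        assert np.allclose(est.scores, 0.0, atol=1e-6)

    def test_sum_zero_constraint(self):
        est = fit_ranking(random_singles_ledger(5, 15, seed=3))
        assert abs(est.scores.sum()) < 1e-8

    def test_matches_mm_oracle_on_singles(self):
        """t=1 ledgers are the classic Bradley-Terry model; the MM algorithm
        is an independent route to the same MLE."""
        for seed in (0, 1, 2):
            ledger = random_singles_ledger(5, 30, seed=seed, rounds=10)
            if not is_strongly_connected(ledger):
                continue
            est = fit_ranking(ledger, ridge=0.0)
            oracle = mm_bradley_terry(ledger)
            assert np.allclose(est.scores, oracle, atol=1e-4)

    def test_matches_grid_oracle_small(self):
        ledger = random_singles_ledger(4, 14, seed=11, rounds=6)
        assert is_strongly_connected(ledger)
        est = fit_ranking(ledger, ridge=0.0)
        oracle = grid_refine_optimum(ledger)
        assert np.max(np.abs(est.scores - oracle)) < 1e-3

    def test_initialization_independence(self):
        """Convexity: optima from two random starts coincide."""
        rng = np.random.default_rng(5)
        ledger = random_singles_ledger(5, 25, seed=8, rounds=10)
        a = fit_ranking(ledger, x0=rng.normal(size=5))
        b = fit_ranking(ledger, x0=rng.normal(size=5))
        assert np.allclose(a.scores, b.scores, atol=1e-6)

    def test_swap_teams_invariance(self):
        ledger = random_singles_ledger(5, 20, seed=13)
        swapped = MatchLedger(
            [
                MatchRecord(m.team_minus, m.team_plus, m.wins_minus, m.wins_plus, m.rounds_played)
                for m in ledger.matches
            ],
            ledger.feature_universe,
            ledger.eval_counts,
        )
        a = fit_ranking(ledger)
        b = fit_ranking(swapped)
        assert np.allclose(a.scores, b.scores, atol=1e-7)

    def test_unseen_feature_excluded_and_flagged(self):
        ledger = single_match_ledger(3.0, 1.0)
        ledger = MatchLedger(ledger.matches, ("a", "b", "ghost"), {})
        with pytest.warns(UserWarning, match="ghost"):
            est = fit_ranking(ledger)
        assert est.excluded == ("ghost",)
        assert "ghost" not in est.feature_universe

    def test_consistency_error_shrinks_with_ledger_size(self):
        """Mean absolute score error decreases when the ledger grows 10x."""
        true = np.array([1.0, 0.5, 0.0, -0.5, -1.0])
        errs_small, errs_big = [], []
        for seed in range(10):
            small = random_singles_ledger(5, 20, seed=seed, true_scores=true, rounds=4)
            big = random_singles_ledger(5, 200, seed=seed + 500, true_scores=true, rounds=4)
            errs_small.append(np.mean(np.abs(fit_ranking(small).scores - true)))
            errs_big.append(np.mean(np.abs(fit_ranking(big).scores - true)))
        assert np.mean(errs_big) < np.mean(errs_small)

    def test_ridge_guards_against_separation(self):
        """A feature winning every match has an infinite MLE; the default
        ridge keeps the fit finite and convergent."""
        est = fit_ranking(single_match_ledger(4.0, 0.0))
        assert np.all(np.isfinite(est.scores))
        assert est.converged


class TestSetStrengthCI:
    def test_singleton_matches_per_feature_se(self):
        est = fit_ranking(random_singles_ledger(5, 20, seed=2))
        strength, se, ci = set_strength_ci(est, FeatureSet(["f1"]))
        assert strength == pytest.approx(est.score_of("f1"))
        assert se == pytest.approx(est.standard_errors[1])
        assert ci[0] <= strength <= ci[1]

    def test_full_universe_strength_zero(self):
        est = fit_ranking(random_singles_ledger(4, 16, seed=4))
        strength, _, _ = set_strength_ci(est, FeatureSet(est.feature_universe))
        assert strength == pytest.approx(0.0, abs=1e-8)

    def test_variance_matches_finite_difference_hessian(self):
        """Delta-method variance equals 1' Cov 1 with Cov from an independent
        finite-difference Hessian of the penalized likelihood."""
        ridge = 1e-4
        ledger = random_singles_ledger(4, 20, seed=6, rounds=10)
        est = fit_ranking(ledger, ridge=ridge)
        names = list(est.feature_universe)

        def nll(v):
            return naive_nll(dict(zip(names, v)), ledger, ridge=ridge)

        H = fd_hessian(nll, est.scores.copy())
        p = len(names)
        P = np.eye(p) - np.full((p, p), 1 / p)
        cov = P @ np.linalg.pinv(P @ H @ P) @ P
        for members in (["f0"], ["f0", "f2"], names[:3]):
            ind = np.array([1.0 if n in members else 0.0 for n in names])
            _, se, _ = set_strength_ci(est, FeatureSet(members))
            expected_var = float(ind @ cov @ ind)
            assert se**2 == pytest.approx(expected_var, rel=0.01)

    def test_unknown_member_rejected(self):
        est = fit_ranking(single_match_ledger())
        with pytest.raises(KeyError):
            set_strength_ci(est, FeatureSet(["nope"]))


class TestSelectTop:
    def _estimate(self, scores, ses, names):
        scores = np.asarray(scores, dtype=float)
        ses = np.asarray(ses, dtype=float)
        from teamrank.ranking import RankingEstimate

        return RankingEstimate(
            feature_universe=tuple(names),
            scores=scores,
            standard_errors=ses,
            ci_lower=scores - ses,
            ci_upper=scores + ses,
            covariance=np.diag(ses**2),
            ci_level=0.95,
        )

    def test_top_by_score(self):
        est = self._estimate([2.0, 1.0, -3.0], [0.1, 0.1, 0.1], ["a", "b", "c"])
        assert list(select_top(est, 2).selected) == ["a", "b"]

    def test_tie_broken_by_se_then_name(self):
        est = self._estimate([1.0, 1.0, 1.0], [0.3, 0.1, 0.3], ["c", "b", "a"])
        assert list(select_top(est, 2).selected) == ["b", "a"]

    def test_m_out_of_range(self):
        est = self._estimate([1.0], [0.1], ["a"])
        with pytest.raises(ValueError):
            select_top(est, 2)
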