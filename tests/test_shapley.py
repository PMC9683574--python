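import numpy as np
import pytest

import shapaal
from shapaal import (
    CoalitionGame,
    compute_norm_stats,
    exact_shapley,
    marginal_contribution,
    model_attribution_values,
    monte_carlo_shapley,
    retrain_value_fn,
    z_normalize,
)
from shapaal.errors import ContractError, FeasibilityError
from conftest import random_game


def additive_game(n):
    return CoalitionGame(n_players=n, value_fn=lambda psi: float(len(psi)))


def with_dummy(n, dummy):
    """Game over n players where `dummy` never changes the worth."""
    rng = np.random.default_rng(99)
    table = {}

    def value_fn(psi):
        key = tuple(p for p in psi if p != dummy)
        if key not in table:
            table[key] = float(rng.normal()) if key else 0.0
        return table[key]

    return CoalitionGame(n_players=n, value_fn=value_fn)


class TestMarginalContribution:
    def test_additive_game_every_marginal_is_one(self):
        g = additive_game(4)
        for psi in [(), (0,), (1, 2), (0, 1, 3)]:
            player = next(p for p in range(4) if p not in psi)
            assert marginal_contribution(g, player, psi) == 1.0

    def test_dummy_player_marginals_are_zero(self):
        g = with_dummy(4, dummy=3)
        for psi in [(), (0,), (0, 1), (0, 1, 2)]:
            assert marginal_contribution(g, 3, psi) == 0.0

    def test_matches_direct_two_call_evaluation(self):
        g = random_game(5, seed=8)
        for player in range(5):
            for psi in [(), tuple(p for p in range(5) if p != player)[:2]]:
                expected = g.value(psi + (player,)) - g.value(psi)
                assert marginal_contribution(g, player, psi) == pytest.approx(expected, abs=1e-12)

    def test_player_in_coalition_rejected(self):
        with pytest.raises(ContractError):
            marginal_contribution(additive_game(3), 1, (1, 2))


class TestExactShapley:
    def test_symmetric_additive_game(self):
        res = exact_shapley(additive_game(3))
        assert np.allclose(res.values, [1.0, 1.0, 1.0], atol=1e-12)

    def test_null_player_gets_exactly_zero(self):
        res = exact_shapley(with_dummy(3, dummy=2))
        assert abs(res.values[2]) <= 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_subset_and_permutation_formulas_agree(self, seed):
        g = random_game(6, seed=seed)
        sub = exact_shapley(g, "subset_formula")
        per = exact_shapley(CoalitionGame(6, g.value), "permutation_enumeration")
        assert np.abs(sub.values - per.values).max() <= 1e-9

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_efficiency_axiom(self, n):
        g = random_game(n, seed=n)
        res = exact_shapley(g)
        assert abs(res.values.sum() - g.value(tuple(range(n)))) <= 1e-9

    def test_linearity_of_exact_values(self):
        gu, gw = random_game(5, seed=1), random_game(5, seed=2)
        gsum = CoalitionGame(5, lambda psi: gu.value(psi) + gw.value(psi))
        assert np.allclose(
            exact_shapley(gsum).values,
            exact_shapley(gu).values + exact_shapley(gw).values,
            atol=1e-9,
        )

    def test_enumeration_caps_raise_feasibility_error(self):
        with pytest.raises(FeasibilityError):
            exact_shapley(additive_game(13), "subset_formula")
        with pytest.raises(FeasibilityError):
            exact_shapley(additive_game(9), "permutation_enumeration")


class TestMonteCarloShapley:
    def test_additive_game_recovered_exactly(self):
        res = monte_carlo_shapley(additive_game(5), 100, seed=0)
        assert np.array_equal(res.values, np.ones(5))
        assert np.array_equal(res.std_errors, np.zeros(5))

    def test_within_three_se_of_exact(self):
        g = random_game(6, seed=3)
        exact = exact_shapley(g).values
        mc = monte_carlo_shapley(CoalitionGame(6, g.value), 5000, seed=1)
        assert np.all(np.abs(mc.values - exact) <= 3 * np.maximum(mc.std_errors, 1e-12))

    def test_seed_determinism(self):
        g1, g2 = random_game(5, seed=4), random_game(5, seed=4)
        a = monte_carlo_shapley(g1, 200, seed=7)
        b = monte_carlo_shapley(g2, 200, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_null_player_within_three_se_of_zero(self):
        mc = monte_carlo_shapley(with_dummy(6, dummy=0), 500, seed=5)
        assert abs(mc.values[0]) <= 3 * max(float(mc.std_errors[0]), 1e-12)

    def test_error_shrinks_with_more_permutations(self):
        g = random_game(6, seed=6)
        exact = exact_shapley(g).values
        errs = []
        for n_perm in (200, 2000):
            mc = monte_carlo_shapley(CoalitionGame(6, g.value), n_perm, seed=2)
            errs.append(np.abs(mc.values - exact).mean())
        assert errs[1] < errs[0]


class TestRetrainValueFunction:
    def test_empty_coalition_is_zero_and_full_is_near_max(self, separable_pair):
        train, test, _ = separable_pair
        st = compute_norm_stats(train)
        game = retrain_value_fn(z_normalize(train, st), z_normalize(test, st))
        assert game.value(()) == 0.0
        counts = np.bincount(test.encoded_labels)
        majority = counts.max() / counts.sum()
        full = game.value(tuple(range(train.n)))
        assert full + majority >= 0.95  # well-separated classes: near-perfect 1-NN

    def test_duplicate_players_receive_equal_exact_values(self, rng):
        x = rng.normal(size=(4, 10))
        x[1] = x[0]  # players 0 and 1 are exact duplicates
        train = shapaal.TimeSeriesDataset(series=x, labels=np.array([1, 1, 2, 2]), role="train")
        eval_set = shapaal.TimeSeriesDataset(
            series=rng.normal(size=(20, 10)), labels=rng.integers(1, 3, size=20), role="train"
        )
        game = retrain_value_fn(train, eval_set)
        res = exact_shapley(game)
        assert res.values[0] == pytest.approx(res.values[1], abs=1e-9)

    def test_train_reuse_must_be_declared(self, separable_pair):
        train, _, _ = separable_pair
        with pytest.raises(ContractError):
            retrain_value_fn(train, train)


class TestModelAttribution:
    @pytest.fixture()
    def fitted(self, separable_pair, fast_model_config):
        train, _, _ = separable_pair
        st = compute_norm_stats(train)
        norm = z_normalize(train, st)
        model = shapaal.build_model(fast_model_config, train.t, 2)
        shapaal.fit(model, norm, norm_stats=st)
        return model, norm

    def test_zeroed_head_gives_all_zero_values(self, fitted):
        model, norm = fitted
        for p in model.network.head.params:
            p[...] = 0.0
        res = model_attribution_values(model, norm, background_size=5, seed=0, n_steps=4)
        assert np.allclose(res.values, 0.0, atol=1e-12)

    def test_duplicated_samples_get_identical_values(self, fitted):
        model, norm = fitted
        dup = shapaal.TimeSeriesDataset(
            series=np.vstack([norm.series[:4], norm.series[0]]),
            labels=np.concatenate([norm.labels[:4], norm.labels[:1]]),
            role="train", label_set=norm.label_set,
        )
        res = model_attribution_values(model, dup, background_size=5, seed=0, n_steps=4)
        assert res.values[0] == pytest.approx(res.values[4], abs=1e-12)

    def test_background_size_contract(self, fitted):
        model, norm = fitted
        with pytest.raises(ContractError):
            model_attribution_values(model, norm, background_size=norm.n + 1, seed=0)

    def test_mislabeled_samples_rank_below_clean(self, mislabeled_pair, fast_model_config):
        """Synthetic enrichment: flipped labels get lower median attribution."""
        train, _, truth = mislabeled_pair
        st = compute_norm_stats(train)
        norm = z_normalize(train, st)
        model = shapaal.build_model(fast_model_config, train.t, 2)
        shapaal.fit(model, norm, norm_stats=st)
        res = model_attribution_values(model, norm, background_size=30, seed=1, n_steps=4)
        mis = np.zeros(train.n, dtype=bool)
        mis[truth.mislabeled_indices] = True
        assert np.median(res.values[mis]) < np.median(res.values[~mis])
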