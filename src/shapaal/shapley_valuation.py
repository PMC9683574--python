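"""Shapley-value worth of training samples in a transferable-utility game.

Each of the N training samples is a player; a coalition's worth v(psi) is the
predictive payoff of a model trained on exactly that subset (shifted so that
v of the empty set is 0). The Shapley value phi(n) of sample n is its
fairness-axiomatic share of the grand coalition's worth: the weighted average
of the marginal contributions v(psi + n) - v(psi) over all coalitions, or
equivalently the average marginal contribution over all player orderings.
Samples with phi(n) <= 0 are null-or-harmful players and become candidates
for discarding.

Estimators provided:

* ``exact_shapley`` — full enumeration, either through the subset-weight
  formula sum |psi|! (N-|psi|-1)! / N! * delta, or by averaging over all N!
  permutations. Feasible for small N only; the two routes cross-check each
  other to 1e-9.
* ``monte_carlo_shapley`` — seeded permutation sampling with per-player
  standard errors; the practical estimator for realistic N.
* ``model_attribution_values`` — the shortcut used in practice: per-sample
  aggregation of gradient-based input attributions of a fitted reference
  model against a background set (integrated gradients, a completeness-
  preserving Shapley approximation). One scalar per training sample: the sum
  over time steps of the attribution of that sample's true-class logit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .data_io import TimeSeriesDataset
from .errors import ContractError, FeasibilityError
from .resnet_model import TrainedModel

SUBSET_CAP = 12
PERMUTATION_CAP = 8


@dataclass
class CoalitionGame:
    """N players and a coalition worth function with v(empty) = 0.

    ``value_fn`` receives a tuple of sorted player indices. Whatever raw
    payoff it returns is shifted by its empty-coalition evaluation, so the
    normalization v(empty) = 0 holds by construction. Evaluations are
    memoized — the subset formula revisits coalitions heavily.
    """

    n_players: int
    value_fn: Callable[[tuple], float]
    cache: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_players < 1:
            raise ContractError("a game needs at least one player")
        self._empty_raw = float(self.value_fn(()))

    def value(self, coalition) -> float:
        key = tuple(sorted(int(i) for i in coalition))
        if len(set(key)) != len(key):
            raise ContractError("coalition contains duplicate players")
        if key and (key[0] < 0 or key[-1] >= self.n_players):
            raise ContractError("coalition contains out-of-range players")
        if key not in self.cache:
            self.cache[key] = float(self.value_fn(key)) - self._empty_raw
        return self.cache[key]


@dataclass(frozen=True)
class MarginalContribution:
    player: int
    coalition: tuple
    delta: float


@dataclass
class ShapleyResult:
    values: np.ndarray
    estimator: str  # exact_subset | exact_permutation | monte_carlo | model_attribution
    n_evaluations: int = 0
    seed: Optional[int] = None
    std_errors: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        has_se = self.std_errors is not None
        if has_se != (self.estimator == "monte_carlo"):
            raise ContractError("std_errors present iff estimator is monte_carlo")


def marginal_contribution(game: CoalitionGame, player: int, coalition) -> float:
    """v(psi + {player}) - v(psi); the player must not already be in psi."""
    psi = tuple(sorted(int(i) for i in coalition))
    if player in psi:
        raise ContractError(f"player {player} already in coalition {psi}")
    return game.value(psi + (player,)) - game.value(psi)


def exact_shapley(game: CoalitionGame, method: str = "subset_formula") -> ShapleyResult:
    """Exact Shapley vector by full enumeration (small N only).

    ``subset_formula`` sums weighted marginal contributions over all
    coalitions excluding each player; ``permutation_enumeration`` averages
    marginal contributions over all N! orderings. Both satisfy efficiency
    (sum phi = v of the grand coalition) to floating-point accuracy.
    """
    n = game.n_players
    if method == "subset_formula":
        if n > SUBSET_CAP:
            raise FeasibilityError(
                f"N={n} exceeds the subset-enumeration cap {SUBSET_CAP}; "
                "use monte_carlo_shapley"
            )
        values = np.zeros(n)
        players = range(n)
        fact = [math.factorial(i) for i in range(n + 1)]
        for player in players:
            others = [p for p in players if p != player]
            total = 0.0
            for size in range(n):
                w = fact[size] * fact[n - size - 1] / fact[n]
                for psi in itertools.combinations(others, size):
                    total += w * marginal_contribution(game, player, psi)
            values[player] = total
        return ShapleyResult(values=values, estimator="exact_subset", n_evaluations=len(game.cache))
    if method == "permutation_enumeration":
        if n > PERMUTATION_CAP:
            raise FeasibilityError(
                f"N={n} exceeds the permutation-enumeration cap {PERMUTATION_CAP}; "
                "use monte_carlo_shapley"
            )
        sums = np.zeros(n)
        count = 0
        for perm in itertools.permutations(range(n)):
            prefix = ()
            for player in perm:
                sums[player] += marginal_contribution(game, player, prefix)
                prefix = tuple(sorted(prefix + (player,)))
            count += 1
        return ShapleyResult(
            values=sums / count, estimator="exact_permutation", n_evaluations=len(game.cache)
        )
    raise ContractError(f"unknown exact method {method!r}")


def monte_carlo_shapley(game: CoalitionGame, n_permutations: int, seed: int) -> ShapleyResult:
    """Permutation-sampling estimate with per-player standard errors.

    Each sampled ordering is scanned left to right, crediting every player
    with its marginal contribution to the preceding prefix. phi-hat is the
    per-player mean over orderings; the SE is the standard error of that
    mean (ddof=1).
    """
    if n_permutations < 2:
        raise ContractError("need at least 2 permutations for a standard error")
    n = game.n_players
    rng = np.random.default_rng(seed)
    samples = np.zeros((n_permutations, n))
    for r in range(n_permutations):
        perm = rng.permutation(n)
        prefix = ()
        prev = game.value(())
        for player in perm:
            prefix = tuple(sorted(prefix + (int(player),)))
            cur = game.value(prefix)
            samples[r, player] = cur - prev
            prev = cur
    values = samples.mean(axis=0)
    std_errors = samples.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return ShapleyResult(
        values=values,
        estimator="monte_carlo",
        n_evaluations=len(game.cache),
        seed=seed,
        std_errors=std_errors,
    )


def retrain_value_fn(
    train: TimeSeriesDataset,
    eval_set: TimeSeriesDataset,
    surrogate: str = "nearest_neighbor",
    *,
    allow_train_reuse: bool = False,
    model_factory: Optional[Callable] = None,
) -> CoalitionGame:
    """Game whose coalition worth is held-out accuracy after retraining.

    v_raw(psi) is the accuracy on ``eval_set`` of the surrogate classifier
    trained on subset psi of ``train``; v_raw(empty) is the majority-class
    baseline of the evaluation labels, and the game shifts by it so
    v(empty) = 0. Surrogates:

    * ``nearest_neighbor`` (default) — 1-NN on Euclidean distance, the cheap
      oracle path. Distances are precomputed once. If ``eval_set`` is the
      training set itself (``allow_train_reuse=True`` declares this), the
      self-match of each instance is excluded, i.e. leave-self-out 1-NN.
    * ``resnet`` — the full residual network (expensive); requires
      ``model_factory() -> (unfitted TrainedModel, fit kwargs)``.
    """
    if eval_set.n < 1:
        raise ContractError("empty evaluation set")
    same_object = eval_set is train
    if same_object and not allow_train_reuse:
        raise ContractError(
            "evaluating on the training set must be declared with allow_train_reuse=True"
        )

    eval_labels = eval_set.labels
    counts = np.bincount(eval_set.encoded_labels)
    majority_baseline = float(counts.max() / counts.sum())

    if surrogate == "nearest_neighbor":
        diff = train.series[:, None, :] - eval_set.series[None, :, :]
        dist = np.einsum("ijk,ijk->ij", diff, diff)  # squared distances, (N_train, N_eval)
        if same_object:
            np.fill_diagonal(dist, np.inf)
        train_labels = train.labels

        def value_fn(psi: tuple) -> float:
            if not psi:
                return majority_baseline
            idx = np.asarray(psi, dtype=np.int64)
            sub = dist[idx]
            pred = train_labels[idx[sub.argmin(axis=0)]]
            usable = np.isfinite(sub.min(axis=0))
            if not usable.any():
                return majority_baseline
            return float((pred[usable] == eval_labels[usable]).mean())

    elif surrogate == "resnet":
        if model_factory is None:
            raise ContractError("resnet surrogate needs a model_factory")
        from .resnet_model import fit as _fit, predict as _predict

        def value_fn(psi: tuple) -> float:
            if not psi:
                return majority_baseline
            model, fit_kwargs = model_factory()
            _fit(model, train.subset(list(psi)), **fit_kwargs)
            _, pred = _predict(model, eval_set)
            return float((pred == eval_labels).mean())

    else:
        raise ContractError(f"unknown surrogate {surrogate!r}")

    return CoalitionGame(n_players=train.n, value_fn=value_fn)


AGGREGATIONS = ("signed_sum", "mean", "true_minus_max_other")


def model_attribution_values(
    model: TrainedModel,
    train: TimeSeriesDataset,
    background_size: int = 50,
    seed: int = 0,
    n_steps: int = 8,
    aggregation: str = "signed_sum",
) -> ShapleyResult:
    """Per-sample worth from gradient attributions of a fitted reference model.

    For each training sample x with true class c, integrated gradients of the
    class-c logit are computed against each of ``background_size`` background
    instances drawn (seeded) from the training set, using an ``n_steps``
    midpoint Riemann sum along the straight path. By completeness the
    per-sample sum of attributions approximates
    logit_c(x) - mean_b logit_c(b): a sample scores positive when the model
    is more confident in its labelled class than it is for a typical
    background input. Aggregation of the T per-time-step attributions to one
    scalar is ``signed_sum`` by default (preserves sign, so the phi <= 0
    discard rule stays meaningful).
    """
    if not model.fitted:
        raise ContractError("attribution needs a fitted reference model")
    if aggregation not in AGGREGATIONS:
        raise ContractError(f"unknown aggregation {aggregation!r}")
    n = train.n
    background_size = int(background_size)
    if background_size > n:
        raise ContractError(f"background_size {background_size} exceeds N={n}")
    if background_size < 1:
        raise ContractError("background_size must be >= 1")
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(n, size=background_size, replace=False)
    bg = train.series[bg_idx]  # (B, T)
    y = train.encoded_labels

    values = np.zeros(n)
    n_eval = 0
    for i in range(n):
        x = train.series[i]
        classes = _attribution_classes(model, y[i], aggregation)
        attr_by_class = {}
        for c in classes:
            # midpoint path points for every background at once: (B*S, T)
            alphas = (np.arange(n_steps) + 0.5) / n_steps
            path = bg[:, None, :] + alphas[None, :, None] * (x[None, None, :] - bg[:, None, :])
            flat = path.reshape(-1, train.t)
            grads = model.input_gradient(flat, np.full(len(flat), c))
            grads = grads.reshape(background_size, n_steps, train.t).mean(axis=1)
            attr = (x[None, :] - bg) * grads  # (B, T)
            attr_by_class[c] = attr.mean(axis=0)  # average over background
            n_eval += len(flat)
        values[i] = _aggregate(attr_by_class, y[i], aggregation)
    return ShapleyResult(
        values=values, estimator="model_attribution", n_evaluations=n_eval, seed=seed
    )


def _attribution_classes(model: TrainedModel, true_class: int, aggregation: str):
    if aggregation == "true_minus_max_other":
        return list(range(model.n_classes))
    return [int(true_class)]


def _aggregate(attr_by_class: dict, true_class: int, aggregation: str) -> float:
    true_attr = attr_by_class[int(true_class)]
    if aggregation == "signed_sum":
        return float(true_attr.sum())
    if aggregation == "mean":
        return float(true_attr.mean())
    other = [a.sum() for c, a in attr_by_class.items() if c != int(true_class)]
    return float(true_attr.sum() - max(other))
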