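"""Learn -> Unlearn -> Re-learn orchestration and the four-variant ablation.

The full pipeline (``run_shapaal``) fits an augmented model M_aug on
perturbed, train-stat-normalized inputs; values every training sample with
M_aug as the reference; discards samples whose value phi(n) <= 0 (the
null-player rule — a boundary that includes exact zeros); and re-fits a
fresh model M_ShapAAL on the perturbed retained subset. Test data is always
clean and normalized with the training statistics.

``run_ablation_study`` evaluates any subset of the four variants over a
list of seeds:

* ``M``         — plain fit on all training data, no perturbation;
* ``M_Shapley`` — fit on the subset selected from a valuation that uses the
                  unperturbed base model M as reference;
* ``M_aug``     — perturbed fit on all training data;
* ``M_ShapAAL`` — the full three-stage pipeline.

Reported accuracies are aggregated by the mode over seeds (ties broken
toward the larger value).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .data_io import TimeSeriesDataset, compute_norm_stats, z_normalize
from .errors import ConfigError, ContractError
from .metrics import mode_accuracy, mpce, test_accuracy
from .perturbation import DEFAULT_ALPHA, PerturbationConfig, perturb, sample_perturbation
from .resnet_model import (
    ResNetConfig,
    TrainedModel,
    build_model,
    estimate_depth,
    fit,
    predict,
)
from .shapley_valuation import (
    ShapleyResult,
    model_attribution_values,
    monte_carlo_shapley,
    retrain_value_fn,
)

VARIANTS = ("M", "M_Shapley", "M_aug", "M_ShapAAL")


@dataclass
class PipelineConfig:
    """Every knob of a full run, serializable for the run manifest."""

    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    model: ResNetConfig = None
    valuation: str = "model_attribution"  # or "retrain_mc"
    background_size: int = 50
    attribution_steps: int = 8
    aggregation: str = "signed_sum"
    n_permutations: int = 100
    surrogate: str = "nearest_neighbor"
    threshold_rule: str = "le"  # discard phi <= 0 ("le") or phi < 0 ("lt")

    def __post_init__(self):
        if self.model is None:
            self.model = ResNetConfig(seed=self.seed)
        if self.valuation not in ("model_attribution", "retrain_mc"):
            raise ConfigError(f"unknown valuation {self.valuation!r}")
        if self.threshold_rule not in ("le", "lt"):
            raise ConfigError(f"threshold_rule must be 'le' or 'lt'")


@dataclass
class AblationResult:
    """Partition of training indices produced by the null-player rule."""

    kept_indices: np.ndarray
    discarded_indices: np.ndarray
    values: ShapleyResult
    rule: str
    fallback_engaged: bool = False

    def __post_init__(self):
        self.kept_indices = np.asarray(self.kept_indices, dtype=np.int64)
        self.discarded_indices = np.asarray(self.discarded_indices, dtype=np.int64)
        n = len(self.values.values)
        union = np.concatenate([self.kept_indices, self.discarded_indices])
        if sorted(union.tolist()) != list(range(n)):
            raise ContractError("kept and discarded must partition all indices")
        if len(self.kept_indices) < 1:
            raise ContractError("at least one sample must be kept")

    @property
    def n_effective(self) -> int:
        return len(self.kept_indices)

    @property
    def n_discarded(self) -> int:
        return len(self.discarded_indices)


def select_subset(
    values: ShapleyResult,
    rule: str = "le",
    labels: Optional[np.ndarray] = None,
) -> AblationResult:
    """Discard every sample whose value fails the null-player threshold.

    ``rule='le'`` discards phi <= 0 (the default; zeros are null players),
    ``rule='lt'`` discards strictly negative values only. If the rule would
    discard everything, a guard keeps the single highest-valued sample per
    class (per label when ``labels`` is given, else the global argmax) and
    flags the run.
    """
    phi = np.asarray(values.values, dtype=np.float64)
    if phi.size == 0:
        raise ContractError("empty value vector")
    if not np.isfinite(phi).all():
        raise ContractError("values must be finite")
    if rule == "le":
        keep_mask = phi > 0
    elif rule == "lt":
        keep_mask = phi >= 0
    else:
        raise ContractError(f"unknown rule {rule!r}")

    fallback = not keep_mask.any()
    if fallback:
        keep_mask = np.zeros_like(keep_mask)
        if labels is not None:
            labels = np.asarray(labels)
            for lab in np.unique(labels):
                cls = np.flatnonzero(labels == lab)
                keep_mask[cls[phi[cls].argmax()]] = True
        else:
            keep_mask[phi.argmax()] = True

    kept = np.flatnonzero(keep_mask)
    discarded = np.flatnonzero(~keep_mask)
    desc = "discard phi <= 0" if rule == "le" else "discard phi < 0"
    if fallback:
        desc += " [fallback: kept per-class argmax]"
    return AblationResult(
        kept_indices=kept,
        discarded_indices=discarded,
        values=values,
        rule=desc,
        fallback_engaged=fallback,
    )


def _prepared_inputs(train, stats, alpha, seed):
    """Perturb raw training series (x + delta), then normalize."""
    pcfg = PerturbationConfig(
        alpha=alpha, mu=stats.mean, sigma2=stats.std**2, seed=seed
    )
    draw = sample_perturbation(pcfg, train.series.shape)
    perturbed = train.replace_series(perturb(train.series, draw))
    return z_normalize(perturbed, stats), pcfg


def _fit_variant(train_norm, stats, config, tag, perturb_cfg=None):
    mcfg = config.model
    if mcfg.n_blocks is None:
        mcfg = replace(mcfg, n_blocks=estimate_depth(train_norm))
    model = build_model(mcfg, train_norm.t, train_norm.n_classes)
    model.variant_tag = tag
    fit(model, train_norm, perturb_cfg=None, norm_stats=stats)
    return model


def _value_samples(config, reference_model, train_for_valuation, clean_norm_train, seed):
    if config.valuation == "model_attribution":
        return model_attribution_values(
            reference_model,
            train_for_valuation,
            background_size=min(train_for_valuation.n, config.background_size),
            seed=seed,
            n_steps=config.attribution_steps,
            aggregation=config.aggregation,
        )
    game = retrain_value_fn(
        clean_norm_train, clean_norm_train, surrogate=config.surrogate, allow_train_reuse=True
    )
    return monte_carlo_shapley(game, n_permutations=config.n_permutations, seed=seed)


def run_shapaal(
    train: TimeSeriesDataset,
    test: TimeSeriesDataset,
    config: PipelineConfig,
):
    """Full three-stage pipeline; returns (M_ShapAAL, AblationResult, metrics).

    Learn: fit M_aug on perturbed + normalized training data. Unlearn: value
    every sample with M_aug as reference and apply the null-player discard
    rule. Re-learn: fit a fresh, re-initialized model on the perturbed +
    normalized retained subset (fresh noise draws, seeded). Evaluation is on
    the clean test set normalized with the training statistics.
    """
    stats = compute_norm_stats(train)
    test_norm = z_normalize(test, stats)

    # Learn
    train_aug, _ = _prepared_inputs(train, stats, config.alpha, seed=config.seed)
    m_aug = _fit_variant(train_aug, stats, config, "M_aug")

    # Unlearn
    clean_norm = z_normalize(train, stats)
    values = _value_samples(config, m_aug, train_aug, clean_norm, seed=config.seed)
    ablation = select_subset(values, rule=config.threshold_rule, labels=train.encoded_labels)

    # Re-learn (fresh model, fresh noise on the retained subset)
    kept = train.subset(ablation.kept_indices, name_suffix="")
    kept_aug, _ = _prepared_inputs(kept, stats, config.alpha, seed=config.seed + 1)
    m_shapaal = _fit_variant(kept_aug, stats, config, "M_ShapAAL")

    probs, pred = predict(m_shapaal, test_norm)
    metrics = {
        "test_accuracy": test_accuracy(pred, test.labels),
        "mpce": mpce(pred, test.labels, n_classes=test.n_classes, labels=test.label_set),
        "n_effective": ablation.n_effective,
        "n_discarded": ablation.n_discarded,
    }
    return m_shapaal, ablation, metrics


@dataclass
class AblationStudyReport:
    """Per-variant accuracies over seeds, all on one shared test set."""

    per_seed_accuracy: dict  # variant -> {seed: accuracy}
    per_seed_mpce: dict
    mode_accuracies: dict  # variant -> mode over seeds
    seeds: list
    ablation: Optional[AblationResult] = None
    config: Optional[PipelineConfig] = None

    def digest(self) -> str:
        payload = json.dumps(
            {
                "acc": {v: sorted(d.items()) for v, d in self.per_seed_accuracy.items()},
                "mpce": {v: sorted(d.items()) for v, d in self.per_seed_mpce.items()},
                "mode": sorted(self.mode_accuracies.items()),
                "seeds": list(self.seeds),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def run_ablation_study(
    train: TimeSeriesDataset,
    test: TimeSeriesDataset,
    config: PipelineConfig,
    variants=VARIANTS,
    seeds=(0,),
) -> AblationStudyReport:
    """Evaluate the requested variants across seeds on one shared test set."""
    variants = tuple(variants)
    seeds = [int(s) for s in seeds]
    if not variants or not seeds:
        raise ContractError("need at least one variant and one seed")
    for v in variants:
        if v not in VARIANTS:
            raise ConfigError(f"unknown variant {v!r}; expected one of {VARIANTS}")

    stats = compute_norm_stats(train)
    test_norm = z_normalize(test, stats)
    clean_norm = z_normalize(train, stats)

    acc = {v: {} for v in variants}
    mp = {v: {} for v in variants}
    last_ablation = None
    for seed in seeds:
        seeded = replace(config, seed=seed, model=replace(config.model, seed=seed))
        for variant in variants:
            if variant == "M":
                model = _fit_variant(clean_norm, stats, seeded, "M")
            elif variant == "M_aug":
                train_aug, _ = _prepared_inputs(train, stats, seeded.alpha, seed=seed)
                model = _fit_variant(train_aug, stats, seeded, "M_aug")
            elif variant == "M_Shapley":
                base = _fit_variant(clean_norm, stats, seeded, "M")
                values = _value_samples(seeded, base, clean_norm, clean_norm, seed=seed)
                ablation = select_subset(
                    values, rule=seeded.threshold_rule, labels=train.encoded_labels
                )
                kept = clean_norm.subset(ablation.kept_indices, name_suffix="")
                model = _fit_variant(kept, stats, seeded, "M_Shapley")
            else:  # M_ShapAAL
                model, last_ablation, _ = run_shapaal(train, test, seeded)
            if variant != "M_ShapAAL":
                _, pred = predict(model, test_norm)
            else:
                _, pred = predict(model, test_norm)
            acc[variant][seed] = test_accuracy(pred, test.labels)
            mp[variant][seed] = mpce(
                pred, test.labels, n_classes=test.n_classes, labels=test.label_set
            )

    modes = {v: mode_accuracy(list(acc[v].values())) for v in variants}
    return AblationStudyReport(
        per_seed_accuracy=acc,
        per_seed_mpce=mp,
        mode_accuracies=modes,
        seeds=seeds,
        ablation=last_ablation,
        config=config,
    )
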