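"""Synthetic labelled time-series benchmarks with known ground truth.

The generator emulates the small-sample benchmark regime the pipeline
targets — N in [20, 200] training instances, lengths T in [24, 301], two or
three classes — using analytically simple class templates (class-specific
sinusoids, or localized Gaussian bumps) plus i.i.d. Gaussian observation
noise. A controllable fraction of training labels can be flipped to a wrong
class; the flipped index set is recorded, giving exact ground truth against
which the null-player discard rule is quantitatively testable. Test labels
are never flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import TimeSeriesDataset
from .errors import ConfigError, ContractError

TEMPLATE_FAMILIES = ("sinusoid", "localized_bump")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic benchmark."""

    n_train: int = 60
    n_test: int = 120
    length_t: int = 96
    n_classes: int = 2
    template_family: str = "sinusoid"
    noise_sd: float = 0.5
    mislabel_fraction: float = 0.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 1:
            raise ConfigError("n_train and n_test must be positive")
        if self.length_t < 2:
            raise ConfigError("length_t must be at least 2")
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.template_family not in TEMPLATE_FAMILIES:
            raise ConfigError(f"unknown template_family {self.template_family!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not (0.0 <= self.mislabel_fraction < 0.5):
            raise ConfigError("mislabel_fraction must lie in [0, 0.5)")
        if self.template_family == "localized_bump" and self.n_classes > self.length_t // 8:
            raise ConfigError("too many classes for distinct bump centers at this length")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """What the generator knows and a downstream method must recover."""

    clean_labels: np.ndarray
    observed_labels: np.ndarray
    mislabeled_indices: np.ndarray
    template_parameters: dict

    def __post_init__(self):
        clean = np.asarray(self.clean_labels)
        obs = np.asarray(self.observed_labels)
        flipped = np.flatnonzero(clean != obs)
        if sorted(flipped.tolist()) != sorted(np.asarray(self.mislabeled_indices).tolist()):
            raise ContractError("observed labels must differ from clean exactly on mislabeled_indices")


def _templates(spec: SyntheticSpec) -> np.ndarray:
    t = np.arange(spec.length_t) / spec.length_t
    out = np.zeros((spec.n_classes, spec.length_t))
    if spec.template_family == "sinusoid":
        for c in range(spec.n_classes):
            freq = c + 1.0  # class-specific frequency, phase staggered
            phase = c * np.pi / 4
            out[c] = np.sin(2 * np.pi * freq * t + phase)
    else:
        width = spec.length_t / (6 * spec.n_classes)
        for c in range(spec.n_classes):
            center = (c + 1) * spec.length_t / (spec.n_classes + 1)
            out[c] = np.exp(-0.5 * ((np.arange(spec.length_t) - center) / width) ** 2)
    return out


def template_parameters(spec: SyntheticSpec) -> dict:
    tpl = _templates(spec)
    return {c: tpl[c] for c in range(spec.n_classes)}


def generate(spec: SyntheticSpec):
    """Build (train, test, truth); every instance is template + noise.

    Labels are 1..C (UCR-style). Exactly floor(rho * n_train) training
    labels are flipped, each to a uniformly chosen wrong class; the flipped
    indices are returned as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    tpl = _templates(spec)

    def draw_split(n):
        labels = rng.integers(0, spec.n_classes, size=n)
        x = tpl[labels] + rng.normal(0.0, spec.noise_sd, size=(n, spec.length_t))
        return x, labels

    x_train, clean = draw_split(spec.n_train)
    x_test, test_labels = draw_split(spec.n_test)

    n_flip = int(np.floor(spec.mislabel_fraction * spec.n_train))
    flip_idx = rng.choice(spec.n_train, size=n_flip, replace=False) if n_flip else np.array([], dtype=np.int64)
    observed = clean.copy()
    for i in flip_idx:
        wrong = [c for c in range(spec.n_classes) if c != clean[i]]
        observed[i] = wrong[rng.integers(len(wrong))]

    label_set = tuple(range(1, spec.n_classes + 1))
    train = TimeSeriesDataset(
        series=x_train,
        labels=observed + 1,
        name=f"{spec.name}_TRAIN",
        role="train",
        label_set=label_set,
    )
    test = TimeSeriesDataset(
        series=x_test,
        labels=test_labels + 1,
        name=f"{spec.name}_TEST",
        role="test",
        label_set=label_set,
    )
    truth = SyntheticGroundTruth(
        clean_labels=clean + 1,
        observed_labels=observed + 1,
        mislabeled_indices=np.sort(flip_idx),
        template_parameters=template_parameters(spec),
    )
    return train, test, truth


def nearest_template_labels(series: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Oracle classifier: assign each series to the closest class template."""
    tpl = _templates(spec)
    d = ((np.asarray(series)[:, None, :] - tpl[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1) + 1


def enrichment_score(ablation, truth: SyntheticGroundTruth) -> float:
    """Precision of the discarded set for true mislabels.

    Fraction of discarded indices that are genuinely mislabeled; the
    random-discard baseline is the mislabel fraction rho. An empty discard
    set scores 0 by convention.
    """
    discarded = np.asarray(ablation.discarded_indices, dtype=np.int64)
    n = len(truth.clean_labels)
    if discarded.size and (discarded.min() < 0 or discarded.max() >= n):
        raise ContractError("discarded indices outside the training index space")
    if discarded.size == 0:
        return 0.0
    mis = set(np.asarray(truth.mislabeled_indices, dtype=np.int64).tolist())
    return float(np.mean([int(i) in mis for i in discarded]))
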