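"""Evaluation metrics: accuracy, mean per-class error, gains, mode-over-seeds.

MPCE (mean per-class error) is the class-balance-aware complement of
accuracy: the per-class error rates err_c are averaged over the C classes,
so a classifier that sacrifices a rare class cannot hide behind overall
accuracy. For perfectly balanced test sets MPCE equals 1 - accuracy exactly.
A per-instance weighted variant (each test instance contributes its own
class's error rate, i.e. classes weighted by their frequency) is available
behind ``form="per_instance"``.

Because neural-network training is not run-to-run stable across backends,
studies here report the mode of the test accuracies over many seeds; ties
are broken toward the larger value.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .errors import ContractError


def test_accuracy(predicted, truth) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ContractError("predicted and truth must be equal-length vectors")
    if predicted.size == 0:
        raise ContractError("empty label vectors")
    return float((predicted == truth).mean())


def per_class_error(predicted, truth, labels) -> dict:
    """err_c = fraction of class-c instances misclassified, per class.

    Classes absent from ``truth`` are skipped (no instances to err on).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    errors = {}
    for lab in labels:
        mask = truth == lab
        if mask.any():
            errors[lab] = float((predicted[mask] != lab).mean())
    return errors


def mpce(predicted, truth, n_classes: int, labels=None, form: str = "per_class") -> float:
    """Mean per-class error.

    ``form="per_class"`` (default): (1/C) * sum_c err_c over the classes
    present in the truth vector (absent classes are excluded and the
    denominator adjusted, with C taken as the number of contributing
    classes). ``form="per_instance"``: the per-instance average of each
    instance's own class error rate.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ContractError("predicted and truth must be equal-length vectors")
    if n_classes < 2:
        raise ContractError("MPCE needs at least 2 classes")
    if labels is None:
        labels = sorted(np.unique(truth).tolist())
    errors = per_class_error(predicted, truth, labels)
    if not errors:
        raise ContractError("no declared class present in truth")
    if form == "per_class":
        return float(np.mean(list(errors.values())))
    if form == "per_instance":
        rates = np.array([errors[int(t)] for t in truth])
        return float(rates.mean())
    raise ContractError(f"unknown MPCE form {form!r}")


def learning_gain(acc_shapaal: float, acc_base: float) -> float:
    """Relative test-accuracy improvement over the base model."""
    if acc_base <= 0:
        raise ContractError("learning gain undefined for non-positive base accuracy")
    return (acc_shapaal - acc_base) / acc_base


def insufficiency_factor(n_train: int, n_test: int) -> float:
    """Training insufficiency factor: N_train / N_test (<= 1 means the model
    is tested on more instances than it ever saw in training)."""
    if n_train < 1 or n_test < 1:
        raise ContractError("counts must be >= 1")
    return n_train / n_test


def differential_gain(acc: float, benchmark: float) -> float:
    """Signed relative difference to a reported benchmark accuracy;
    positive means the benchmark is outperformed."""
    if benchmark <= 0:
        raise ContractError("benchmark must be positive")
    return (acc - benchmark) / benchmark


def mode_accuracy(per_seed_accuracies, rounding: int = 4) -> float:
    """Most frequent accuracy after rounding; ties go to the larger value."""
    vals = [round(float(a), rounding) for a in per_seed_accuracies]
    if not vals:
        raise ContractError("empty accuracy vector")
    counts = Counter(vals)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]
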