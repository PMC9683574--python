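"""Reading, writing and normalizing labelled univariate time-series datasets.

The on-disk format is the UCR-archive dialect: one instance per line, an
integer class label followed by T real values, separated by tabs, commas or
whitespace. Train and test splits are fixed and exclusive; z-normalization of
the test split always reuses the statistics of its paired training split,
because at deployment time the test distribution is unknown.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContractError,
    DegenerateScaleError,
    EmptyInputError,
    FormatError,
    ParseError,
)

#: below this pooled standard deviation the data is treated as constant
STD_FLOOR = 1e-12


def _strip_split_suffix(name: str) -> str:
    return re.sub(r"_(train|test)$", "", name, flags=re.IGNORECASE)


@dataclass
class TimeSeriesDataset:
    """N labelled series of identical length T.

    ``labels`` holds the original integer labels from the source (e.g. the
    -1/1 coding some archive datasets use); ``encoded_labels`` exposes the
    stable contiguous 0..C-1 coding used internally by the models.
    """

    series: np.ndarray  # (N, T) float64
    labels: np.ndarray  # (N,) int64, original label values
    name: str = ""
    role: str = "train"  # "train" | "test"
    label_set: tuple = field(default=None)  # sorted original labels

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.series.ndim != 2:
            raise FormatError("series must be a 2-D (N, T) matrix")
        if self.n == 0:
            raise EmptyInputError("dataset has no instances")
        if self.t < 2:
            raise FormatError("series length T must be at least 2")
        if self.labels.shape != (self.n,):
            raise FormatError("labels must be a length-N vector")
        if not np.isfinite(self.series).all():
            raise FormatError("series contain missing or non-finite values")
        if self.role not in ("train", "test"):
            raise ContractError(f"role must be 'train' or 'test', got {self.role!r}")
        if self.label_set is None:
            self.label_set = tuple(sorted(np.unique(self.labels).tolist()))
        else:
            self.label_set = tuple(sorted(self.label_set))
            declared = set(self.label_set)
            if not declared.issuperset(self.labels.tolist()):
                raise FormatError("labels outside the declared label set")

    @property
    def n(self) -> int:
        return self.series.shape[0]

    @property
    def t(self) -> int:
        return self.series.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.label_set)

    @property
    def encoded_labels(self) -> np.ndarray:
        """Labels recoded to 0..C-1 following the sorted original values."""
        lookup = {lab: i for i, lab in enumerate(self.label_set)}
        return np.array([lookup[int(l)] for l in self.labels], dtype=np.int64)

    def decode(self, encoded: np.ndarray) -> np.ndarray:
        """Map 0..C-1 codes back to the original label values."""
        table = np.asarray(self.label_set, dtype=np.int64)
        return table[np.asarray(encoded, dtype=np.int64)]

    def subset(self, indices, name_suffix: str = "_subset") -> "TimeSeriesDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return TimeSeriesDataset(
            series=self.series[idx].copy(),
            labels=self.labels[idx].copy(),
            name=self.name + name_suffix,
            role=self.role,
            label_set=self.label_set,
        )

    def replace_series(self, series: np.ndarray) -> "TimeSeriesDataset":
        return TimeSeriesDataset(
            series=series,
            labels=self.labels.copy(),
            name=self.name,
            role=self.role,
            label_set=self.label_set,
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Scalar mean/std pooled over every entry of a training matrix."""

    mean: float
    std: float
    source: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.mean) and np.isfinite(self.std)):
            raise ContractError("normalization statistics must be finite")
        if self.std < STD_FLOOR:
            raise DegenerateScaleError(
                f"std {self.std!r} below floor {STD_FLOOR}; data is (near-)constant"
            )


def _detect_separator(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace split


def read_ucr(path, dialect: str = "auto", role: str = "train", name: str = None) -> TimeSeriesDataset:
    """Read a UCR-dialect file: one ``label v1 ... vT`` record per line.

    ``dialect`` is "auto" (default: per-file detection), "tab", "comma" or
    "whitespace". Row order is preserved; labels keep their original values.
    """
    with open(path, "r") as fh:
        raw_lines = fh.read().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw_lines) if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty file")

    sep = {"auto": _detect_separator(lines[0][1]), "tab": "\t", "comma": ",", "whitespace": None}[dialect]

    rows, labels = [], []
    width = None
    for lineno, ln in lines:
        fields = [f for f in ln.split(sep) if f.strip() != ""]
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: need a label and at least 2 values")
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {width})"
            )
        try:
            lab = float(fields[0])
            vals = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if lab != int(lab):
            raise ParseError(f"{path}:{lineno}: class label {fields[0]!r} is not an integer")
        labels.append(int(lab))
        rows.append(vals)

    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return TimeSeriesDataset(
        series=np.array(rows, dtype=np.float64),
        labels=np.array(labels, dtype=np.int64),
        name=name,
        role=role,
    )


def write_ucr(dataset: TimeSeriesDataset, path, sep: str = "\t"):
    """Write a dataset in the UCR dialect, re-readable by :func:`read_ucr`.

    Values use Python's shortest round-trip float representation, so
    ``read_ucr(write_ucr(ds))`` reproduces ``ds.series`` bit for bit and a
    second write is byte-identical.
    """
    lines = []
    for lab, row in zip(dataset.labels, dataset.series):
        lines.append(sep.join([str(int(lab))] + [repr(float(v)) for v in row]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def compute_norm_stats(train: TimeSeriesDataset) -> NormalizationStats:
    """Scalar mean/std pooled over all N*T entries of the training matrix.

    The population (divide-by-N) convention is used. Statistics are only ever
    computed from a training split.
    """
    if train.role != "train":
        raise ContractError("normalization statistics must come from a training split")
    flat = train.series.ravel()
    if np.unique(flat).size < 2:
        raise DegenerateScaleError("training matrix is constant; cannot z-normalize")
    mean = float(flat.mean())
    std = float(flat.std())  # population convention, ddof=0
    return NormalizationStats(mean=mean, std=std, source=train.name)


def z_normalize(dataset: TimeSeriesDataset, stats: NormalizationStats) -> TimeSeriesDataset:
    """Apply the affine map ``(x - mean)/std`` entry-wise; labels untouched.

    Test data must be normalized with the statistics of its paired training
    split: when both names are non-empty the train/test pairing is checked by
    base name (the ``_TRAIN``/``_TEST`` suffix convention).
    """
    if dataset.role == "test" and dataset.name and stats.source:
        if _strip_split_suffix(dataset.name) != _strip_split_suffix(stats.source):
            raise ContractError(
                f"test set {dataset.name!r} normalized with stats from unpaired "
                f"source {stats.source!r}; use the paired training statistics"
            )
    return dataset.replace_series((dataset.series - stats.mean) / stats.std)
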