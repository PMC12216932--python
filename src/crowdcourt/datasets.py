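"""Dataset generation, loading, splitting and single-model learning curves.

The ensemble experiments need a balanced two-class problem that a small
classifier learns *slowly* — if a judge trained on a handful of samples were
already near-perfect, committees could never reveal a finite optimal group
size.  The built-in generator produces a noisy concentric-circles problem in
2-D (outer ring class 0, inner ring at radius ``factor`` class 1); any
user-supplied tabular binary-classification CSV can be used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidInputError, InvalidParameterError

__all__ = [
    "LabeledDataset",
    "SplitPair",
    "LearningCurve",
    "make_circles_clusters",
    "split_train_test",
    "load_and_preprocess_tabular",
    "learning_curve",
    "balanced_bootstrap_indices",
]

#: Default train share of the train/test split (3:7).
DEFAULT_TRAIN_FRACTION = 0.3

#: Default Gaussian displacement of the circles generator.  Chosen so a
#: single small-sample classifier climbs slowly from chance and plateaus
#: below 1.0 — the slow learning-curve regime the experiments require.
DEFAULT_CIRCLES_NOISE = 0.1


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels.

    ``features`` is an ``(n, d)`` float array, ``labels`` an ``(n,)`` array
    with values in {0, 1}.
    """

    features: np.ndarray
    labels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise InvalidInputError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise InvalidInputError("labels length must match feature rows")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise InvalidInputError(f"labels must be in {{0, 1}}, got {sorted(uniq)}")
        self.labels = self.labels.astype(int)

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def class_counts(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in (0, 1)}

    def subset(self, indices: np.ndarray, name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            self.features[indices], self.labels[indices], name or self.name
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.features, columns=[f"x{i}" for i in range(self.n_features)]
        )
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SplitPair:
    """Disjoint train/test partition of a parent dataset."""

    train: LabeledDataset
    test: LabeledDataset
    ratio: tuple[float, float]
    split_seed: int | None = None


@dataclass
class LearningCurve:
    """Mean and spread of single-model test accuracy vs training-set size.

    One point per entry of ``sample_sizes``; ``repeats`` random balanced
    subsamplings per point.
    """

    sample_sizes: list[int]
    mean_accuracy: list[float]
    std: list[float]
    repeats: int

    def __post_init__(self) -> None:
        n = len(self.sample_sizes)
        if len(self.mean_accuracy) != n or len(self.std) != n:
            raise InvalidParameterError("learning-curve field lengths differ")
        if any(s < 0 for s in self.std):
            raise InvalidParameterError("std must be non-negative")
        if self.repeats < 1:
            raise InvalidParameterError("repeats must be >= 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_size": self.sample_sizes,
                "mean_accuracy": self.mean_accuracy,
                "std": self.std,
                "repeats": self.repeats,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def make_circles_clusters(
    n_samples: int,
    factor: float = 0.85,
    noise_sd: float = DEFAULT_CIRCLES_NOISE,
    seed: int | None = None,
    angles: str = "uniform",
) -> LabeledDataset:
    """Two noisy concentric circles in 2-D.

    ``ceil(n/2)`` points sit on the unit circle (class 0) and ``floor(n/2)``
    on a circle of radius ``factor`` (class 1); every point is displaced by
    isotropic Gaussian noise of scale ``noise_sd``.  Angles are drawn
    uniformly (``angles="uniform"``) or equally spaced (``"spaced"``).

    With ``factor`` close to 1 and non-trivial noise the rings overlap and
    the problem is learned slowly, which is the regime of interest.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    if not (0.0 < factor < 1.0):
        raise InvalidParameterError(f"factor must lie in (0, 1), got {factor!r}")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if angles not in ("uniform", "spaced"):
        raise InvalidParameterError("angles must be 'uniform' or 'spaced'")

    rng = np.random.default_rng(seed)
    n_out = int(np.ceil(n_samples / 2))
    n_in = n_samples - n_out

    def _angles(n: int) -> np.ndarray:
        if angles == "spaced":
            return np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        return rng.uniform(0.0, 2 * np.pi, size=n)

    theta_out, theta_in = _angles(n_out), _angles(n_in)
    outer = np.column_stack([np.cos(theta_out), np.sin(theta_out)])
    inner = factor * np.column_stack([np.cos(theta_in), np.sin(theta_in)])
    X = np.vstack([outer, inner])
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    y = np.concatenate([np.zeros(n_out, dtype=int), np.ones(n_in, dtype=int)])
    return LabeledDataset(X, y, name=f"circles(factor={factor}, noise={noise_sd})")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_test(
    data: LabeledDataset,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    stratified: bool = False,
    seed: int | None = None,
) -> SplitPair:
    """Random disjoint train/test split with ``floor`` rounding.

    The train side gets exactly ``floor(train_fraction * n)`` samples (the
    rule consistent with a 3:7 split of both 5,000 and 54,035 records); the
    test side gets the rest.  The stratified variant applies the floor rule
    per class and then tops up from the classes with the largest fractional
    remainders until the global train size is reached.
    """
    if not (0.0 < train_fraction < 1.0):
        raise InvalidParameterError("train_fraction must lie in (0, 1)")
    n = len(data)
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise InvalidParameterError(
            f"split of {n} samples at fraction {train_fraction} leaves an empty side"
        )
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        takes, remainders = {}, {}
        for c in (0, 1):
            n_c = int((data.labels == c).sum())
            exact = train_fraction * n_c
            takes[c] = int(np.floor(exact))
            remainders[c] = exact - takes[c]
        short = n_train - sum(takes.values())
        for c in sorted(remainders, key=remainders.get, reverse=True)[: max(0, short)]:
            takes[c] += 1
        train_parts, test_parts = [], []
        for c in (0, 1):
            idx_c = np.flatnonzero(data.labels == c)
            idx_c = rng.permutation(idx_c)
            train_parts.append(idx_c[: takes[c]])
            test_parts.append(idx_c[takes[c]:])
        train_idx = rng.permutation(np.concatenate(train_parts))
        test_idx = rng.permutation(np.concatenate(test_parts))

    return SplitPair(
        train=data.subset(train_idx, name=f"{data.name}[train]"),
        test=data.subset(test_idx, name=f"{data.name}[test]"),
        ratio=(train_fraction, 1.0 - train_fraction),
        split_seed=seed,
    )


# ---------------------------------------------------------------------------
# Tabular loading
# ---------------------------------------------------------------------------

def load_and_preprocess_tabular(
    path,
    label_column: str,
    standardize: bool = True,
    label_mapping: Mapping | None = None,
) -> LabeledDataset:
    """Load a CSV with a binary label column into a :class:`LabeledDataset`.

    Numeric feature columns are z-scored (fit on the full table) when
    ``standardize`` is set; constant columns are dropped with a warning
    (z-scoring them would divide by zero).  Labels are mapped to {0, 1}
    either via ``label_mapping`` or, for a two-valued column, by sorted
    order; the applied mapping is recorded in the dataset name.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise InvalidInputError(f"label column {label_column!r} not in {path}")
    raw_labels = df[label_column]
    feats = df.drop(columns=[label_column])

    non_numeric = [c for c in feats.columns if not pd.api.types.is_numeric_dtype(feats[c])]
    if non_numeric:
        raise InvalidInputError(
            f"non-numeric feature columns without a stated encoding: {non_numeric}"
        )

    if label_mapping is None:
        values = sorted(pd.unique(raw_labels).tolist())
        if len(values) != 2:
            raise InvalidInputError(
                f"label column must be binary, found {len(values)} distinct values"
            )
        label_mapping = {values[0]: 0, values[1]: 1}
    labels = raw_labels.map(label_mapping)
    if labels.isna().any() or not set(labels.unique()) <= {0, 1}:
        raise InvalidInputError("label mapping does not yield values in {0, 1}")

    constant = [c for c in feats.columns if feats[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant feature columns {constant} (zero variance)",
            UserWarning,
            stacklevel=2,
        )
        feats = feats.drop(columns=constant)
    if feats.shape[1] == 0:
        raise InvalidInputError("no usable feature columns remain")

    X = feats.to_numpy(dtype=float)
    if standardize:
        from sklearn.preprocessing import StandardScaler

        X = StandardScaler().fit_transform(X)
    return LabeledDataset(
        X, labels.to_numpy(dtype=int), name=f"{path}:{label_column}->{dict(label_mapping)}"
    )


# ---------------------------------------------------------------------------
# Balanced bootstrap and learning curves
# ---------------------------------------------------------------------------

def balanced_bootstrap_indices(
    labels: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-balanced bootstrap draw of size ``n``.

    Sampling is with replacement; class 0 receives ``floor(n/2)`` samples
    and class 1 the remaining ``ceil(n/2)``.
    """
    if n < 1:
        raise InvalidParameterError("bootstrap size must be >= 1")
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise DegenerateDataError("both classes must be present for a balanced draw")
    n0 = n // 2
    n1 = n - n0
    picked = np.concatenate([rng.choice(idx0, n0), rng.choice(idx1, n1)])
    rng.shuffle(picked)
    return picked


def learning_curve(
    spec,
    data: LabeledDataset | SplitPair,
    sample_sizes: Sequence[int],
    repeats: int = 100,
    seed: int | None = None,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
) -> LearningCurve:
    """Single-model test accuracy vs balanced training-set size.

    For each size ``s``: ``repeats`` iterations of (balanced bootstrap draw
    of ``s`` samples from the train partition, train one classifier from
    ``spec``, score on the test partition); the mean and standard deviation
    over repeats are reported (``std = 0`` for a single repeat).

    ``data`` may be a pre-made :class:`SplitPair` or a full dataset, which
    is then split at ``train_fraction``.
    """
    from .ensemble import ClassifierSpec  # deferred: avoids a module cycle

    if not isinstance(spec, ClassifierSpec):
        raise InvalidParameterError("spec must be a ClassifierSpec")
    sizes = [int(s) for s in sample_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise InvalidParameterError("sample_sizes must be positive")
    if repeats < 1:
        raise InvalidParameterError("repeats must be >= 1")

    ss = np.random.SeedSequence(seed)
    if isinstance(data, SplitPair):
        pair = data
    else:
        pair = split_train_test(
            data, train_fraction=train_fraction, seed=int(ss.generate_state(1)[0] % 2**31)
        )
    rng = np.random.default_rng(ss.spawn(1)[0])

    means, stds = [], []
    for s in sizes:
        accs = np.empty(repeats)
        for r in range(repeats):
            idx = balanced_bootstrap_indices(pair.train.labels, s, rng)
            model = spec.build(seed=int(rng.integers(2**31)))
            model.fit(pair.train.features[idx], pair.train.labels[idx])
            accs[r] = float(
                (model.predict(pair.test.features) == pair.test.labels).mean()
            )
        means.append(float(accs.mean()))
        stds.append(float(accs.std(ddof=0)) if repeats > 1 else 0.0)
    return LearningCurve(
        sample_sizes=sizes, mean_accuracy=means, std=stds, repeats=repeats
    )
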