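"""Correlated-cue population model of collective decision making.

A group of ``N`` members faces a sequence of binary decision problems.  For
each problem the group is composed afresh: every member is, independently
with probability ``p``, an *independent* unit that reads a low-correlation
environmental cue and is correct with probability ``r_L`` on its own; the
remaining members are *dependent* units that all follow one shared
high-correlation cue, drawn once per problem and correct with probability
``r_H`` — so every dependent member casts the same vote.  The group verdict
is the strict majority, with exact ties broken by a fair coin.

Because dependent members vote as a single bloc, the effective jury can be
much smaller than ``N``, and collective accuracy need not improve with group
size.  Low-correlated members form an effective majority only when

    p > 1 / (2 r_L),

the critical boundary separating the wisdom-of-crowds regime (accuracy is
maximised by the largest group) from the breakdown regime (a finite group
size is optimal).

The module provides a Monte-Carlo simulator, an exact closed-form oracle
obtained by conditioning on the group composition and the shared-cue draw,
an optimal-group-size search, and (reliability, p) phase diagrams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import InvalidParameterError

__all__ = [
    "SyntheticParams",
    "AccuracyEstimate",
    "AccuracyCurve",
    "PhaseDiagram",
    "simulate_decisions",
    "exact_accuracy",
    "optimal_group_size",
    "critical_p",
    "phase_diagram",
]

#: Default cap on the group sizes searched when locating the optimum.
DEFAULT_N_MAX = 100

#: Accuracies closer than this are treated as tied when locating the
#: optimal group size (ties break toward the smallest N).
_ACC_TIE_TOL = 1e-10


def _check_prob(x: float, name: str) -> float:
    x = float(x)
    if not (0.0 <= x <= 1.0) or not np.isfinite(x):
        raise InvalidParameterError(f"{name} must lie in [0, 1], got {x!r}")
    return x


def _check_positive_int(x: int, name: str) -> int:
    if isinstance(x, bool) or (not isinstance(x, (int, np.integer)) and float(x) != int(x)):
        raise InvalidParameterError(f"{name} must be a positive integer, got {x!r}")
    x = int(x)
    if x < 1:
        raise InvalidParameterError(f"{name} must be >= 1, got {x}")
    return x


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the correlated-cue population.

    Parameters
    ----------
    p
        Probability that a group member is an independent (low-correlation
        cue) unit.
    r_L
        Probability an independent unit decides correctly.  Canonical range
        [0.5, 1]; values below 0.5 are permitted but warned about.
    r_H
        Probability the shared high-correlation cue is correct.  Same
        canonical range and warning as ``r_L``.
    """

    p: float
    r_L: float
    r_H: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", _check_prob(self.p, "p"))
        object.__setattr__(self, "r_L", _check_prob(self.r_L, "r_L"))
        object.__setattr__(self, "r_H", _check_prob(self.r_H, "r_H"))
        for name in ("r_L", "r_H"):
            if getattr(self, name) < 0.5:
                warnings.warn(
                    f"{name}={getattr(self, name)} lies below 0.5, outside the "
                    "canonical reliability range [0.5, 1]",
                    UserWarning,
                    stacklevel=3,
                )


@dataclass(frozen=True)
class AccuracyEstimate:
    """Monte-Carlo estimate of collective accuracy.

    ``std_error`` is the binomial standard error
    ``sqrt(value * (1 - value) / decisions)``.
    """

    value: float
    decisions: int
    std_error: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", _check_prob(self.value, "value"))
        object.__setattr__(
            self, "decisions", _check_positive_int(self.decisions, "decisions")
        )
        se = float(np.sqrt(self.value * (1.0 - self.value) / self.decisions))
        if self.std_error is None:
            object.__setattr__(self, "std_error", se)
        elif abs(float(self.std_error) - se) > 1e-12:
            raise InvalidParameterError(
                f"std_error {self.std_error} inconsistent with value/decisions "
                f"(expected {se})"
            )


@dataclass
class AccuracyCurve:
    """Collective accuracy as a function of group size.

    ``accuracies`` holds either exact probabilities (floats), Monte-Carlo
    :class:`AccuracyEstimate` objects, or ``(mean, std)`` pairs from repeated
    runs; ``dispersion`` (when present) carries the per-point standard
    deviation across runs.
    """

    group_sizes: list[int]
    accuracies: list
    dispersion: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.accuracies):
            raise InvalidParameterError("group_sizes and accuracies lengths differ")
        if self.dispersion is not None and len(self.dispersion) != len(self.group_sizes):
            raise InvalidParameterError("dispersion length differs from group_sizes")
        sizes = [int(n) for n in self.group_sizes]
        if any(n < 1 for n in sizes):
            raise InvalidParameterError("all group sizes must be >= 1")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise InvalidParameterError("group_sizes must be strictly increasing")
        self.group_sizes = sizes

    @property
    def values(self) -> np.ndarray:
        """Accuracy values as a plain float array."""
        return np.array(
            [a.value if isinstance(a, AccuracyEstimate) else float(a) for a in self.accuracies]
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"N": self.group_sizes, "accuracy": self.values})
        if self.dispersion is not None:
            df["std"] = list(self.dispersion)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class PhaseDiagram:
    """Optimal group size and maximum accuracy over a parameter grid.

    ``x_axis`` is the reliability-like axis (cue reliability ``r_L`` here;
    training-set size ``n_L`` in the ensemble counterpart), ``y_axis`` the
    independence probability ``p``.  ``optimal_N`` and ``max_accuracy`` are
    2-D arrays of shape ``(len(y_axis), len(x_axis))``.
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    optimal_N: np.ndarray
    max_accuracy: np.ndarray
    N_max: int
    x_name: str = "r_L"

    def __post_init__(self) -> None:
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.optimal_N = np.asarray(self.optimal_N, dtype=int)
        self.max_accuracy = np.asarray(self.max_accuracy, dtype=float)
        shape = (len(self.y_axis), len(self.x_axis))
        if self.optimal_N.shape != shape or self.max_accuracy.shape != shape:
            raise InvalidParameterError("grid arrays inconsistent with axes")
        if self.optimal_N.size and (
            self.optimal_N.min() < 1 or self.optimal_N.max() > self.N_max
        ):
            raise InvalidParameterError("optimal_N out of [1, N_max]")
        if self.max_accuracy.size and (
            self.max_accuracy.min() < -1e-12 or self.max_accuracy.max() > 1 + 1e-12
        ):
            raise InvalidParameterError("max_accuracy out of [0, 1]")

    def breakdown_mask(self) -> np.ndarray:
        """True where the optimum is an interior group size (breakdown regime).

        Wisdom of crowds holds in a cell when the accuracy-maximising group
        size is the largest searched (``N_max``, or ``N_max - 1`` to allow
        the even/odd tie under the fair-coin rule).
        """
        return self.optimal_N < self.N_max - 1

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for iy, p in enumerate(self.y_axis):
            for ix, x in enumerate(self.x_axis):
                rows.append(
                    {
                        self.x_name: x,
                        "p": p,
                        "optimal_N": int(self.optimal_N[iy, ix]),
                        "max_accuracy": float(self.max_accuracy[iy, ix]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "x_name": self.x_name,
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "optimal_N": self.optimal_N.tolist(),
            "max_accuracy": self.max_accuracy.tolist(),
            "N_max": int(self.N_max),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Monte-Carlo simulator
# ---------------------------------------------------------------------------

def simulate_decisions(
    params: SyntheticParams,
    N: int,
    M: int,
    seed: int | np.random.Generator | None = None,
) -> AccuracyEstimate:
    """Simulate ``M`` independent decision problems for a group of size ``N``.

    For each problem the group composition is redrawn (each member is
    independent with probability ``p``), the shared cue is drawn once
    (correct with probability ``r_H``) and fixes every dependent vote, each
    independent member votes correctly with probability ``r_L`` on its own,
    and the verdict is the strict majority with fair-coin ties.

    Returns the fraction of correct verdicts with its binomial standard
    error.  Bit-reproducible for a given integer ``seed``.
    """
    if not isinstance(params, SyntheticParams):
        raise InvalidParameterError("params must be a SyntheticParams")
    N = _check_positive_int(N, "N")
    M = _check_positive_int(M, "M")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_indep = rng.binomial(N, params.p, size=M)
    correct_indep = rng.binomial(n_indep, params.r_L)
    cue_correct = rng.random(M) < params.r_H
    correct_votes = correct_indep + (N - n_indep) * cue_correct

    wins = correct_votes * 2 > N
    ties = correct_votes * 2 == N
    if ties.any():
        wins = wins | (ties & (rng.random(M) < 0.5))
    value = float(wins.mean())
    return AccuracyEstimate(value=value, decisions=M)


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------

def _majority_win_prob(k: int, r: float, threshold: float) -> float:
    """P(j > threshold) + P(j == threshold)/2 for j ~ Binomial(k, r)."""
    if threshold < 0:
        return 1.0
    if float(threshold).is_integer():
        t = int(threshold)
        return float(binom.sf(t, k, r) + 0.5 * binom.pmf(t, k, r))
    return float(binom.sf(int(np.floor(threshold)), k, r))


def exact_accuracy(params: SyntheticParams, N: int) -> float:
    """Exact collective accuracy, by conditioning.

    Conditions on the number of independents ``k ~ Binomial(N, p)`` and on
    the shared-cue draw.  Given ``k`` independents of which ``j ~
    Binomial(k, r_L)`` vote correctly, the verdict is correct iff
    ``j + (N - k) * [cue correct] > N/2`` (exact ties count one half, the
    fair-coin convention shared with the simulator).
    """
    if not isinstance(params, SyntheticParams):
        raise InvalidParameterError("params must be a SyntheticParams")
    N = _check_positive_int(N, "N")
    p, r_L, r_H = params.p, params.r_L, params.r_H

    ks = np.arange(N + 1)
    weights = binom.pmf(ks, N, p)
    half = N / 2.0
    acc = 0.0
    for k, w in zip(ks, weights):
        if w == 0.0:
            continue
        n_dep = N - k
        win_if_cue_good = _majority_win_prob(int(k), r_L, half - n_dep)
        win_if_cue_bad = _majority_win_prob(int(k), r_L, half)
        acc += w * (r_H * win_if_cue_good + (1.0 - r_H) * win_if_cue_bad)
    return float(min(1.0, max(0.0, acc)))


def optimal_group_size(
    params: SyntheticParams, N_max: int = DEFAULT_N_MAX
) -> tuple[int, float]:
    """Group size maximising exact collective accuracy, over N = 1..N_max.

    Ties (within ``1e-10``) break toward the smallest group.
    """
    N_max = _check_positive_int(N_max, "N_max")
    accs = np.array([exact_accuracy(params, N) for N in range(1, N_max + 1)])
    best = accs.max()
    n_star = int(np.argmax(accs >= best - _ACC_TIE_TOL)) + 1
    return n_star, float(accs[n_star - 1])


def critical_p(r_L: float) -> float:
    """Critical independence probability ``1 / (2 r_L)``.

    Above this boundary independent members form an effective voting
    majority and the wisdom of crowds can hold.  Values above 1 (possible
    only for ``r_L < 0.5``) are clipped to 1: the boundary then lies outside
    the feasible range of ``p``.
    """
    r_L = _check_prob(r_L, "r_L")
    if r_L == 0.0:
        raise InvalidParameterError("critical_p undefined for r_L = 0")
    return min(1.0, 1.0 / (2.0 * r_L))


def phase_diagram(
    r_L_grid: Sequence[float],
    p_grid: Sequence[float],
    r_H: float,
    N_max: int = DEFAULT_N_MAX,
    mode: str = "exact",
    M: int | None = None,
    seed: int | None = None,
) -> PhaseDiagram:
    """Optimal group size and maximum accuracy over an (r_L, p) grid.

    ``mode="exact"`` evaluates the closed-form oracle per cell;
    ``mode="simulate"`` replaces it by Monte-Carlo averages over ``M``
    decision problems per group size.  The critical boundary is not drawn
    here — retrieve it with :func:`critical_p`.
    """
    r_L_grid = np.asarray(list(r_L_grid), dtype=float)
    p_grid = np.asarray(list(p_grid), dtype=float)
    if r_L_grid.size == 0 or p_grid.size == 0:
        raise InvalidParameterError("grids must be non-empty")
    r_H = _check_prob(r_H, "r_H")
    N_max = _check_positive_int(N_max, "N_max")
    if mode not in ("exact", "simulate"):
        raise InvalidParameterError(f"mode must be 'exact' or 'simulate', got {mode!r}")
    if mode == "simulate":
        if M is None:
            raise InvalidParameterError("mode='simulate' requires M")
        M = _check_positive_int(M, "M")

    ss = np.random.SeedSequence(seed)
    opt = np.zeros((p_grid.size, r_L_grid.size), dtype=int)
    acc = np.zeros_like(opt, dtype=float)
    for iy, p in enumerate(p_grid):
        for ix, r_L in enumerate(r_L_grid):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                params = SyntheticParams(p=p, r_L=r_L, r_H=r_H)
            if mode == "exact":
                opt[iy, ix], acc[iy, ix] = optimal_group_size(params, N_max)
            else:
                rng = np.random.default_rng(ss.spawn(1)[0])
                accs = np.array(
                    [
                        simulate_decisions(params, N, M, rng).value
                        for N in range(1, N_max + 1)
                    ]
                )
                n_star = int(np.argmax(accs)) + 1
                opt[iy, ix], acc[iy, ix] = n_star, float(accs[n_star - 1])
    return PhaseDiagram(
        x_axis=r_L_grid, y_axis=p_grid, optimal_N=opt, max_accuracy=acc, N_max=N_max
    )
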