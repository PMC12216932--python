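"""Committees of classifier judges with controlled training-data correlation.

The machine-learning counterpart of the correlated-cue population model.
Two rosters of binary classifiers are trained on one dataset:

* ``L`` *independent* judges, each fitted to its own class-balanced
  bootstrap draw of ``n_L`` training observations — the analogue of voters
  reading diverse low-correlation cues;
* ``H`` *dependent* judges, fitted to (mostly) shared data — the analogue
  of voters following one high-correlation cue.  Each dependent judge
  trains on the union of a pool-wide shared draw of ``round(alpha * n_H)``
  observations and a per-judge draw of the remainder; ``alpha = 1`` is full
  correlation, ``alpha = 0`` makes dependents effectively independent.

Each test sample is an independent court *hearing*: ``N`` seats are filled
— each seat from the independent roster with probability ``p``, judges
drawn without replacement within a roster — every seated judge predicts the
sample, and the strict-majority verdict is recorded (fair-coin ties).
Rosters are trained once per experiment and reused across hearings; only
seating and voting are repeated.

Sweeping group size, ``n_L`` and ``p`` maps where the committee's accuracy
peaks at a finite group size (wisdom-of-crowds breakdown) versus growing
monotonically.  Bernoulli stub judges (:func:`make_stub_pool`) replace the
trained models by coin flips with prescribed reliabilities, which reduces
the whole hearing machinery to the closed-form population model and is the
bridge used to validate it.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .datasets import LabeledDataset, balanced_bootstrap_indices
from .errors import (
    DegenerateDataError,
    InvalidInputError,
    InvalidParameterError,
    SeatingInfeasibleError,
)
from .population import AccuracyCurve, PhaseDiagram
from .seeding import derive_seeds

__all__ = [
    "EnsembleParams",
    "ClassifierSpec",
    "Judge",
    "StubJudge",
    "JudgePool",
    "ConfusionCounts",
    "HearingRecord",
    "train_judge_pool",
    "make_stub_pool",
    "convene_hearing",
    "run_hearings",
    "accuracy_vs_group_size",
    "ensemble_phase_map",
    "decorrelation_experiment",
    "boundary_vs_nH",
    "dump_hearing_records",
    "mean_pairwise_agreement",
]


def _check_prob(x, name):
    x = float(x)
    if not (0.0 <= x <= 1.0) or not np.isfinite(x):
        raise InvalidParameterError(f"{name} must lie in [0, 1], got {x!r}")
    return x


def _check_pos_int(x, name):
    if isinstance(x, bool) or (not isinstance(x, (int, np.integer)) and float(x) != int(x)):
        raise InvalidParameterError(f"{name} must be a positive integer, got {x!r}")
    x = int(x)
    if x < 1:
        raise InvalidParameterError(f"{name} must be >= 1, got {x}")
    return x


def _shared_count(alpha: float, n_H: int) -> int:
    # round-half-up so the shared + individual portions always sum to n_H
    return int(np.floor(alpha * n_H + 0.5))


@dataclass(frozen=True)
class EnsembleParams:
    """The full parameter set of the committee experiment.

    ``L``/``H`` are roster sizes, ``p`` the per-seat probability of seating
    an independent judge, ``n_L``/``n_H`` the per-judge training-sample
    counts, ``N`` the seats per hearing, ``M`` the number of hearings (test
    set size), and ``alpha`` the shared fraction of dependent training data.
    """

    L: int
    H: int
    p: float
    n_L: int
    n_H: int
    N: int
    M: int
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("L", "H", "n_L", "n_H", "N", "M"):
            object.__setattr__(self, name, _check_pos_int(getattr(self, name), name))
        object.__setattr__(self, "p", _check_prob(self.p, "p"))
        object.__setattr__(self, "alpha", _check_prob(self.alpha, "alpha"))
        if self.N > self.L + self.H:
            raise SeatingInfeasibleError(
                f"rosters (L={self.L}, H={self.H}) can never seat N={self.N} "
                "distinct judges"
            )
        if self.L < self.N or self.H < self.N:
            # extreme all-one-roster compositions are then unseatable; the
            # realized Binomial(N, p) composition must fit the rosters
            warnings.warn(
                f"N={self.N} exceeds a roster (L={self.L}, H={self.H}); "
                "seat compositions a roster cannot hold will be redrawn",
                UserWarning,
                stacklevel=3,
            )

    @property
    def shared_n_H(self) -> int:
        """Size of the pool-wide shared portion of dependent training data."""
        return _shared_count(self.alpha, self.n_H)


@dataclass(frozen=True)
class ClassifierSpec:
    """Recipe for one judge's underlying classifier.

    ``kind`` selects the model family; ``hyperparameters`` are passed to the
    constructor.  ``train_seed_policy`` controls residual stochasticity
    among judges trained on identical data: ``"per-judge"`` (default) gives
    every judge its own training seed, ``"fixed"`` forces determinism so
    same-data judges are exact clones.
    """

    kind: str = "decision_tree"
    hyperparameters: dict = field(default_factory=dict)
    train_seed_policy: str = "per-judge"
    constructor: Callable | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("decision_tree", "rbf_svm", "custom"):
            raise InvalidParameterError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "custom" and self.constructor is None:
            raise InvalidParameterError("custom kind requires a constructor")
        if self.train_seed_policy not in ("fixed", "per-judge"):
            raise InvalidParameterError(
                f"train_seed_policy must be 'fixed' or 'per-judge', "
                f"got {self.train_seed_policy!r}"
            )

    def build(self, seed: int):
        """Instantiate an unfitted classifier with the given training seed."""
        if self.kind == "decision_tree":
            from sklearn.tree import DecisionTreeClassifier

            return DecisionTreeClassifier(random_state=seed, **self.hyperparameters)
        if self.kind == "rbf_svm":
            from sklearn.svm import SVC

            return SVC(kernel="rbf", random_state=seed, **self.hyperparameters)
        return self.constructor(seed=seed, **self.hyperparameters)

    def describe(self) -> dict:
        return {
            "kind": self.kind,
            "hyperparameters": dict(self.hyperparameters),
            "train_seed_policy": self.train_seed_policy,
        }


class _HearingContext:
    """Per-hearing state passed to stochastic (stub) judges."""

    __slots__ = ("truth", "rng", "shared_bits")

    def __init__(self, truth: int, rng: np.random.Generator):
        self.truth = truth
        self.rng = rng
        self.shared_bits: dict = {}


@dataclass
class Judge:
    """A fitted classifier acting as one voter.

    Two judges with identical training data, spec and training seed are
    interchangeable: they produce identical predictions.
    """

    role: str  # "independent" | "dependent"
    training_set_id: str
    model: object
    train_seed: int
    stochastic: bool = False  # True only for stubs whose votes are per-hearing draws
    train_indices: np.ndarray | None = None  # provenance: rows of the training draw

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(X), dtype=int)

    def vote(self, x: np.ndarray, ctx: _HearingContext) -> int:
        return int(self.model.predict(x.reshape(1, -1))[0])


@dataclass
class StubJudge(Judge):
    """A probabilistic judge: correct with probability ``reliability``.

    Independent stubs flip their own coin per hearing; stubs sharing a
    ``shared_key`` all follow one coin flipped once per hearing — exactly
    the dependent-unit rule of the population model.  Used to validate the
    hearing machinery against the closed-form oracle.
    """

    reliability: float = 0.5
    shared_key: str | None = None

    def __init__(self, role: str, reliability: float, shared_key: str | None = None):
        super().__init__(
            role=role,
            training_set_id=f"stub:{role}:{reliability}",
            model=None,
            train_seed=0,
            stochastic=True,
        )
        self.reliability = _check_prob(reliability, "reliability")
        self.shared_key = shared_key

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        raise InvalidInputError("stub judges vote per hearing, not per batch")

    def vote(self, x: np.ndarray, ctx: _HearingContext) -> int:
        if self.shared_key is None:
            correct = ctx.rng.random() < self.reliability
        else:
            if self.shared_key not in ctx.shared_bits:
                ctx.shared_bits[self.shared_key] = bool(
                    ctx.rng.random() < self.reliability
                )
            correct = ctx.shared_bits[self.shared_key]
        return ctx.truth if correct else 1 - ctx.truth


@dataclass
class JudgePool:
    """The two trained rosters plus the provenance needed to rebuild them."""

    independents: list[Judge]
    dependents: list[Judge]
    spec: ClassifierSpec | None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._vote_cache: dict = {}

    @property
    def L(self) -> int:
        return len(self.independents)

    @property
    def H(self) -> int:
        return len(self.dependents)

    @property
    def stochastic(self) -> bool:
        return any(
            j.stochastic for j in self.independents + self.dependents
        )

    def vote_matrices(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cached per-judge predictions on a test matrix.

        Returns ``(ind, dep)`` integer arrays of shapes ``(L, m)`` and
        ``(H, m)``.  Only valid for deterministic (trained-model) judges.
        """
        if self.stochastic:
            raise InvalidInputError("vote matrices undefined for stub pools")
        key = hashlib.blake2b(np.ascontiguousarray(X).tobytes(), digest_size=16).digest()
        if key not in self._vote_cache:
            ind = np.array([j.predict_batch(X) for j in self.independents])
            dep = np.array([j.predict_batch(X) for j in self.dependents])
            self._vote_cache[key] = (ind, dep)
        return self._vote_cache[key]


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix counts accumulated over hearings."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise InvalidParameterError("no hearings recorded")
        return (self.TP + self.TN) / self.total

    def record(self, verdict: int, truth: int) -> None:
        if truth == 1:
            if verdict == 1:
                self.TP += 1
            else:
                self.FN += 1
        else:
            if verdict == 0:
                self.TN += 1
            else:
                self.FP += 1


@dataclass
class HearingRecord:
    """Audit record of a single hearing."""

    sample_index: int
    seats: list[tuple[str, int]]  # (role, roster index) per seat
    votes: list[int]
    verdict: int
    truth: int
    tie_broken: bool = False

    def to_dict(self) -> dict:
        return {
            "sample_index": self.sample_index,
            "seats": [list(s) for s in self.seats],
            "votes": self.votes,
            "verdict": self.verdict,
            "truth": self.truth,
            "tie_broken": self.tie_broken,
        }


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _set_id(idx: np.ndarray) -> str:
    return hashlib.blake2b(
        np.asarray(idx, dtype=np.int64).tobytes(), digest_size=8
    ).hexdigest()


def train_judge_pool(
    train_data: LabeledDataset,
    spec: ClassifierSpec,
    params: EnsembleParams,
    seed: int | None = None,
) -> JudgePool:
    """Train both rosters from one training partition.

    Independents each get a private balanced bootstrap draw of ``n_L``
    observations; dependents share one balanced draw of
    ``round(alpha * n_H)`` observations, topped up per judge to ``n_H``.
    The feature set is identical for every judge.  Reproducible given
    ``seed``.
    """
    if not isinstance(train_data, LabeledDataset):
        raise InvalidInputError("train_data must be a LabeledDataset")
    counts = train_data.class_counts
    if counts[0] == 0 or counts[1] == 0:
        raise DegenerateDataError("training data must contain both classes")

    pool_seed, fixed_seed = derive_seeds(seed, 2)
    rng = np.random.default_rng(pool_seed)

    def _train_seed() -> int:
        if spec.train_seed_policy == "fixed":
            return fixed_seed
        return int(rng.integers(2**31))

    def _fit(idx: np.ndarray, role: str) -> Judge:
        ts = _train_seed()
        model = spec.build(seed=ts)
        model.fit(train_data.features[idx], train_data.labels[idx])
        return Judge(
            role=role, training_set_id=_set_id(idx), model=model,
            train_seed=ts, train_indices=idx,
        )

    independents = [
        _fit(balanced_bootstrap_indices(train_data.labels, params.n_L, rng), "independent")
        for _ in range(params.L)
    ]

    shared_n = params.shared_n_H
    indiv_n = params.n_H - shared_n
    shared_idx = (
        balanced_bootstrap_indices(train_data.labels, shared_n, rng)
        if shared_n > 0
        else np.empty(0, dtype=int)
    )
    dependents = []
    for _ in range(params.H):
        own = (
            balanced_bootstrap_indices(train_data.labels, indiv_n, rng)
            if indiv_n > 0
            else np.empty(0, dtype=int)
        )
        dependents.append(_fit(np.concatenate([shared_idx, own]), "dependent"))

    provenance = {
        "seed": seed,
        "params": {k: getattr(params, k) for k in
                   ("L", "H", "p", "n_L", "n_H", "N", "M", "alpha")},
        "spec": spec.describe(),
        "train_name": train_data.name,
        "shared_set_id": _set_id(shared_idx) if shared_n > 0 else None,
    }
    return JudgePool(independents, dependents, spec, provenance)


def make_stub_pool(L: int, H: int, r_L: float, r_H: float) -> JudgePool:
    """Rosters of Bernoulli stub judges with prescribed reliabilities.

    Independent stubs are correct i.i.d. with probability ``r_L``; all
    dependent stubs follow one shared Bernoulli(``r_H``) draw per hearing.
    Seated in hearings, this pool realises the population model exactly.
    """
    L = _check_pos_int(L, "L")
    H = _check_pos_int(H, "H")
    independents = [StubJudge("independent", r_L) for _ in range(L)]
    dependents = [StubJudge("dependent", r_H, shared_key="cue") for _ in range(H)]
    return JudgePool(
        independents, dependents, spec=None,
        provenance={"stub": True, "r_L": r_L, "r_H": r_H},
    )


# ---------------------------------------------------------------------------
# Hearings
# ---------------------------------------------------------------------------

def convene_hearing(
    pool: JudgePool,
    p: float,
    N: int,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[str, int]]:
    """Randomly seat ``N`` judges for one hearing.

    The number of independent seats is Binomial(``N``, ``p``); within each
    roster judges are drawn without replacement.  A drawn composition that a
    roster cannot seat (possible only when ``N`` exceeds that roster) is
    redrawn; if no composition is feasible a
    :class:`~crowdcourt.errors.SeatingInfeasibleError` is raised.  Returns
    ``(role, roster index)`` pairs.
    """
    _check_prob(p, "p")
    N = _check_pos_int(N, "N")
    k_lo, k_hi = max(0, N - pool.H), min(N, pool.L)
    if k_lo > k_hi or (p == 0.0 and k_lo > 0) or (p == 1.0 and k_hi < N):
        raise SeatingInfeasibleError(
            f"cannot seat N={N} from rosters of L={pool.L}, H={pool.H} at p={p}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(rng.binomial(N, p))
    while not (k_lo <= k <= k_hi):  # conditional redraw, rarely binding
        k = int(rng.binomial(N, p))
    ind_sel = rng.choice(pool.L, size=k, replace=False)
    dep_sel = rng.choice(pool.H, size=N - k, replace=False)
    return [("independent", int(i)) for i in ind_sel] + [
        ("dependent", int(i)) for i in dep_sel
    ]


def run_hearings(
    pool: JudgePool,
    test_data: LabeledDataset,
    p: float,
    N: int,
    seed: int | None = None,
    return_records: bool = True,
) -> tuple[ConfusionCounts, list[HearingRecord] | None]:
    """One freshly convened hearing per test sample.

    Each seated judge predicts the single sample of its hearing; the
    strict-majority verdict (fair-coin ties) is scored against the true
    label.  For trained pools the per-judge predictions are computed once
    per test matrix and reused, which leaves the per-hearing work to
    seating and counting.
    """
    if not isinstance(test_data, LabeledDataset):
        raise InvalidInputError("test_data must be a LabeledDataset")
    expected_d = getattr(pool, "provenance", {}).get("n_features")
    for judge in pool.independents[:1]:
        model = judge.model
        if model is not None and hasattr(model, "n_features_in_"):
            expected_d = int(model.n_features_in_)
    if expected_d is not None and test_data.n_features != expected_d:
        raise InvalidInputError(
            f"test data has {test_data.n_features} features, judges were "
            f"trained on {expected_d}"
        )

    rng = np.random.default_rng(derive_seeds(seed, 1)[0])
    counts = ConfusionCounts()
    records: list[HearingRecord] | None = [] if return_records else None
    use_matrix = not pool.stochastic
    if use_matrix:
        ind_votes, dep_votes = pool.vote_matrices(test_data.features)

    for i in range(len(test_data)):
        truth = int(test_data.labels[i])
        seats = convene_hearing(pool, p, N, rng)
        if use_matrix:
            votes = [
                int(ind_votes[idx, i]) if role == "independent" else int(dep_votes[idx, i])
                for role, idx in seats
            ]
        else:
            ctx = _HearingContext(truth, rng)
            votes = [
                (pool.independents[idx] if role == "independent" else pool.dependents[idx])
                .vote(test_data.features[i], ctx)
                for role, idx in seats
            ]
        ones = sum(votes)
        tie = 2 * ones == N
        if tie:
            verdict = int(rng.random() < 0.5)
        else:
            verdict = int(2 * ones > N)
        counts.record(verdict, truth)
        if records is not None:
            records.append(
                HearingRecord(
                    sample_index=i, seats=seats, votes=votes,
                    verdict=verdict, truth=truth, tie_broken=tie,
                )
            )
    return counts, records


# ---------------------------------------------------------------------------
# Experiments over group size and parameter grids
# ---------------------------------------------------------------------------

def accuracy_vs_group_size(
    pool: JudgePool,
    test_data: LabeledDataset,
    p: float,
    group_sizes: Sequence[int],
    runs: int = 20,
    seed: int | None = None,
) -> AccuracyCurve:
    """Mean and spread of collective accuracy over group sizes.

    The pool is trained once and reused; each of the ``runs`` repetitions
    re-convenes seating for all hearings with a fresh sub-seed.
    """
    sizes = [_check_pos_int(n, "group size") for n in group_sizes]
    runs = _check_pos_int(runs, "runs")
    if max(sizes) > pool.L + pool.H:
        raise SeatingInfeasibleError(
            f"largest group size {max(sizes)} exceeds total roster capacity "
            f"L+H = {pool.L + pool.H}"
        )
    sub_seeds = derive_seeds(seed, len(sizes) * runs)
    means, stds = [], []
    for j, N in enumerate(sizes):
        accs = np.empty(runs)
        for r in range(runs):
            counts, _ = run_hearings(
                pool, test_data, p, N,
                seed=sub_seeds[j * runs + r], return_records=False,
            )
            accs[r] = counts.accuracy
        means.append(float(accs.mean()))
        stds.append(float(accs.std(ddof=0)))
    return AccuracyCurve(group_sizes=sizes, accuracies=means, dispersion=stds)


def _optimal_from_curve(curve: AccuracyCurve, tol: float = 1e-12) -> tuple[int, float]:
    vals = curve.values
    best = vals.max()
    i = int(np.argmax(vals >= best - tol))
    return curve.group_sizes[i], float(vals[i])


def ensemble_phase_map(
    train_data: LabeledDataset,
    test_data: LabeledDataset,
    spec: ClassifierSpec,
    n_L_grid: Sequence[int],
    p_grid: Sequence[float],
    n_H: int,
    N_max: int,
    runs: int,
    seed: int | None = None,
    L: int = 200,
    H: int = 50,
    alpha: float = 1.0,
    group_sizes: Sequence[int] | None = None,
    progress: Callable[[dict], None] | None = None,
) -> PhaseDiagram:
    """Optimal group size and maximum accuracy over an (n_L, p) grid.

    Per cell: train fresh rosters with the cell's ``n_L``, sweep group
    sizes (``1..N_max`` unless a coarser ``group_sizes`` list is given),
    average over ``runs`` seatings, and record the accuracy-maximising
    group size (smallest-N tie-break).  A cell is in the wisdom-of-crowds
    regime when that optimum is the largest size searched.
    """
    n_L_grid = [int(v) for v in n_L_grid]
    p_grid = [float(v) for v in p_grid]
    if not n_L_grid or not p_grid:
        raise InvalidParameterError("grids must be non-empty")
    N_max = _check_pos_int(N_max, "N_max")
    sizes = [int(n) for n in group_sizes] if group_sizes is not None else list(
        range(1, N_max + 1)
    )
    if max(sizes) > N_max:
        raise InvalidParameterError("group_sizes exceed N_max")
    cell_seeds = derive_seeds(seed, 2 * len(n_L_grid) * len(p_grid))

    opt = np.zeros((len(p_grid), len(n_L_grid)), dtype=int)
    acc = np.zeros_like(opt, dtype=float)
    c = 0
    for iy, p in enumerate(p_grid):
        for ix, n_L in enumerate(n_L_grid):
            params = EnsembleParams(
                L=L, H=H, p=p, n_L=n_L, n_H=n_H,
                N=max(sizes), M=len(test_data), alpha=alpha,
            )
            pool = train_judge_pool(train_data, spec, params, seed=cell_seeds[2 * c])
            curve = accuracy_vs_group_size(
                pool, test_data, p, sizes, runs=runs, seed=cell_seeds[2 * c + 1]
            )
            opt[iy, ix], acc[iy, ix] = _optimal_from_curve(curve)
            if progress is not None:
                progress(
                    {
                        "n_L": n_L, "p": p,
                        "optimal_N": int(opt[iy, ix]),
                        "max_accuracy": float(acc[iy, ix]),
                    }
                )
            c += 1
    return PhaseDiagram(
        x_axis=np.array(n_L_grid, dtype=float), y_axis=np.array(p_grid),
        optimal_N=opt, max_accuracy=acc, N_max=N_max, x_name="n_L",
    )


def decorrelation_experiment(
    train_data: LabeledDataset,
    test_data: LabeledDataset,
    spec: ClassifierSpec,
    params: EnsembleParams,
    alphas: Sequence[float],
    group_sizes: Sequence[int],
    runs: int = 20,
    seed: int | None = None,
) -> dict[float, AccuracyCurve]:
    """Accuracy-vs-group-size curves for a family of shared fractions.

    For each ``alpha`` the dependent roster is rebuilt with the
    shared/individual split; the pool seed and hearing seeds are common to
    all alphas, so ``alpha = 1`` reproduces the base experiment exactly.
    """
    alphas = [float(a) for a in alphas]
    if any(not (0.0 <= a <= 1.0) for a in alphas):
        raise InvalidParameterError("alphas must lie in [0, 1]")
    pool_seed, hearing_seed = derive_seeds(seed, 2)
    curves: dict[float, AccuracyCurve] = {}
    for a in alphas:
        pool = train_judge_pool(
            train_data, spec, replace(params, alpha=a), seed=pool_seed
        )
        curves[a] = accuracy_vs_group_size(
            pool, test_data, params.p, group_sizes, runs=runs, seed=hearing_seed
        )
    return curves


@dataclass
class BoundaryResult:
    """Breakdown-region summary for one dependent training-set size."""

    n_H: int
    mask: np.ndarray  # True where the wisdom of crowds breaks down
    area: int  # cell count of the breakdown region
    diagram: PhaseDiagram


def boundary_vs_nH(
    train_data: LabeledDataset,
    test_data: LabeledDataset,
    spec: ClassifierSpec,
    n_L_grid: Sequence[int],
    p_grid: Sequence[float],
    n_H_list: Sequence[int],
    N_max: int,
    runs: int,
    seed: int | None = None,
    **phase_kwargs,
) -> list[BoundaryResult]:
    """How the breakdown region shrinks as dependent judges see more data.

    One phase map per ``n_H``; the breakdown mask and its area (cell count)
    are reported for each.
    """
    n_H_list = [int(v) for v in n_H_list]
    if not n_H_list:
        raise InvalidParameterError("n_H_list must be non-empty")
    seeds = derive_seeds(seed, len(n_H_list))
    out = []
    for s, n_H in zip(seeds, n_H_list):
        diagram = ensemble_phase_map(
            train_data, test_data, spec, n_L_grid, p_grid, n_H,
            N_max=N_max, runs=runs, seed=s, **phase_kwargs,
        )
        mask = diagram.breakdown_mask()
        out.append(BoundaryResult(n_H=n_H, mask=mask, area=int(mask.sum()), diagram=diagram))
    return out


def dump_hearing_records(records: Sequence[HearingRecord], path) -> None:
    """Write hearing records to a JSON-lines audit file."""
    import json

    with open(path, "w") as fh:
        for record in records:
            fh.write(json.dumps(record.to_dict()) + "\n")


def mean_pairwise_agreement(judges: Sequence[Judge], X: np.ndarray) -> float:
    """Mean fraction of samples on which pairs of judges vote identically."""
    if len(judges) < 2:
        raise InvalidParameterError("need at least two judges")
    votes = np.array([j.predict_batch(X) for j in judges], dtype=float)
    total, pairs = 0.0, 0
    for i in range(len(judges)):
        for j in range(i + 1, len(judges)):
            total += float((votes[i] == votes[j]).mean())
            pairs += 1
    return total / pairs
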