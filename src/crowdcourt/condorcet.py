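"""Closed-form Condorcet jury analytics.

A jury of ``N`` voters, each independently correct with probability ``q``,
decides by simple majority.  The probability that the majority is correct is

    P(D) = sum_{k > N/2} C(N, k) q^k (1 - q)^(N - k),

the upper tail of a Binomial(N, q) past the half-way point.  For ``q > 1/2``
this tends to 1 as ``N`` grows — the classical wisdom-of-crowds limit — and
the rate of convergence is what the rest of the package probes when voter
independence is broken.

Ties can only occur for even ``N``.  Two conventions are supported:

* ``"strict"`` — a tie counts as an incorrect group decision (the literal
  strict-majority sum above);
* ``"random"`` — a tie is broken by a fair coin, adding ``P(K = N/2) / 2``.
  Under this convention an even jury of size ``N`` is exactly as good as an
  odd jury of size ``N - 1`` (the classical jury identity).

Evaluation goes through the regularized-incomplete-beta tail of
:class:`scipy.stats.binom`, which is stable for group sizes well beyond 10^4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .errors import InvalidParameterError

__all__ = ["JurySpec", "majority_probability", "convergence_profile"]

_TIE_RULES = ("strict", "random")


def _check_q(q: float) -> float:
    q = float(q)
    if not (0.0 <= q <= 1.0) or not np.isfinite(q):
        raise InvalidParameterError(f"competence q must lie in [0, 1], got {q!r}")
    return q


def _check_N(N: int) -> int:
    if isinstance(N, bool) or (not isinstance(N, (int, np.integer)) and float(N) != int(N)):
        raise InvalidParameterError(f"group size N must be a positive integer, got {N!r}")
    N = int(N)
    if N < 1:
        raise InvalidParameterError(f"group size N must be >= 1, got {N}")
    return N


def _check_tie_rule(tie_rule: str) -> str:
    if tie_rule not in _TIE_RULES:
        raise InvalidParameterError(
            f"tie_rule must be one of {_TIE_RULES}, got {tie_rule!r}"
        )
    return tie_rule


@dataclass(frozen=True)
class JurySpec:
    """A homogeneous-competence voting group.

    Parameters
    ----------
    q
        Per-voter probability of a correct decision, in [0, 1].
    N
        Number of voters (positive integer).
    """

    q: float
    N: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _check_q(self.q))
        object.__setattr__(self, "N", _check_N(self.N))


def majority_probability(spec: JurySpec, tie_rule: str = "strict") -> float:
    """Probability that a simple majority of the jury is correct.

    Parameters
    ----------
    spec
        The jury (competence ``q``, size ``N``).
    tie_rule
        ``"strict"`` counts even-``N`` ties as incorrect; ``"random"``
        resolves them by a fair coin.

    Returns
    -------
    float
        The majority-correctness probability, in [0, 1].
    """
    if not isinstance(spec, JurySpec):
        spec = JurySpec(*spec)
    _check_tie_rule(tie_rule)
    q, N = spec.q, spec.N
    # strict majority: k > N/2, i.e. k >= floor(N/2) + 1
    prob = float(binom.sf(N // 2, N, q))
    if tie_rule == "random" and N % 2 == 0:
        prob += 0.5 * float(binom.pmf(N // 2, N, q))
    return min(1.0, max(0.0, prob))


def convergence_profile(
    q: float,
    group_sizes: Sequence[int] | Iterable[int],
    tie_rule: str = "strict",
) -> list[float]:
    """Majority-correctness probability over a range of group sizes.

    Element-wise :func:`majority_probability` in the order given; used to
    trace how fast (or whether) the large-group certainty limit is reached.
    """
    sizes = list(group_sizes)
    if not sizes:
        raise InvalidParameterError("group_sizes must be non-empty")
    return [majority_probability(JurySpec(q, N), tie_rule) for N in sizes]
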