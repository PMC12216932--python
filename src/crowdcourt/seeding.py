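"""Deterministic sub-seed derivation.

All public entry points take one integer root seed; child seeds for pools,
hearings, cells and runs are derived from it with a fixed counter scheme so
that identical roots give bit-identical experiments.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seeds"]


def derive_seeds(seed: int | None, n: int) -> list[int]:
    """``n`` reproducible integer sub-seeds (each < 2**31) from a root seed."""
    words = np.random.SeedSequence(seed).generate_state(n, np.uint32)
    return [int(w) % 2**31 for w in words]
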