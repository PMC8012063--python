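"""Shared helpers for drawing resampling-null index sets.

All nulls in this package are built from repeated draws of gene indices,
each draw without replacement within itself and independent of the other
draws.  The batched sampler below uses exact rejection sampling (redraw
rows that contain a duplicate) when collisions are rare, which is the
common regime (set size << background size), and falls back to per-row
`Generator.choice` otherwise.  Rejection of with-replacement rows
conditioned on distinctness yields the exact without-replacement law.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_index_matrix", "as_seed_sequence"]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int/None/SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def sample_index_matrix(
    rng: np.random.Generator, n: int, m: int, n_draws: int
) -> np.ndarray:
    """Draw `n_draws` index sets of size `m` from range(n), each without
    replacement within the set.

    Returns an (n_draws, m) integer array.
    """
    if m > n:
        raise ValueError(f"cannot draw {m} distinct indices from {n}")
    if m == n:
        # Every draw is the full background (order is irrelevant to the
        # symmetric statistics computed on the rows).
        return np.tile(np.arange(n), (n_draws, 1))

    expected_collisions = m * (m - 1) / (2.0 * n)
    if expected_collisions <= 0.5:
        idx = rng.integers(0, n, size=(n_draws, m))
        if m > 1:
            while True:
                srt = np.sort(idx, axis=1)
                bad = (np.diff(srt, axis=1) == 0).any(axis=1)
                n_bad = int(bad.sum())
                if n_bad == 0:
                    break
                idx[bad] = rng.integers(0, n, size=(n_bad, m))
        return idx

    # Dense regime: collisions too frequent for rejection to pay off.
    out = np.empty((n_draws, m), dtype=np.int64)
    for j in range(n_draws):
        out[j] = rng.choice(n, size=m, replace=False)
    return out
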