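"""Genomic window arithmetic.

All coordinates in this package are 0-based, half-open.  Windows tile a
sequence span left to right; a final partial window is kept as its own
window when it covers at least half a window size, otherwise it is merged
into the previous window (so the last window may be up to 1.5x the nominal
size and no window is shorter than half the nominal size, except when the
whole span is shorter than one window).
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_windows", "assign_windows"]


def make_windows(length: int, size: int) -> np.ndarray:
    """Tile ``[0, length)`` with windows of nominal ``size``.

    Returns an ``(n, 2)`` int array of ``(start, end)`` pairs.
    """
    if length <= 0:
        raise ValueError(f"span length must be positive, got {length}")
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    n_full, rem = divmod(length, size)
    if n_full == 0:
        return np.array([[0, length]], dtype=np.int64)
    starts = np.arange(n_full, dtype=np.int64) * size
    wins = np.column_stack([starts, starts + size])
    if rem:
        if rem * 2 >= size:
            wins = np.vstack([wins, [[n_full * size, length]]])
        else:
            wins[-1, 1] = length
    return wins


def assign_windows(positions: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Map each position to the index of the window containing it.

    Positions outside the tiled span get index -1.
    """
    positions = np.asarray(positions)
    idx = np.searchsorted(windows[:, 0], positions, side="right") - 1
    ok = (idx >= 0) & (positions < windows[np.clip(idx, 0, len(windows) - 1), 1])
    return np.where(ok, idx, -1)
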