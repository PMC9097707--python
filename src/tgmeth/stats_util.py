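"""Small shared statistical primitives."""

from __future__ import annotations

import numpy as np


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with exact halves going up (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)
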