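"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately use naive elementwise double loops — not the package's
vectorized paths — so they can serve as an independent check.
"""

import numpy as np


def brute_force_rp(states: np.ndarray, norm: str) -> np.ndarray:
    """O(N^2 m) double-loop distance matrix."""
    n = states.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = states[i] - states[j]
            if norm == "l1":
                out[i, j] = np.sum(np.abs(d))
            elif norm == "l2":
                out[i, j] = np.sqrt(np.sum(d * d))
            elif norm == "l2sq":
                out[i, j] = np.sum(d * d)
            elif norm == "linf":
                out[i, j] = np.max(np.abs(d))
            else:
                raise ValueError(norm)
    return out


def brute_force_sign_mask(states: np.ndarray) -> np.ndarray:
    """Double-loop sign of the summed componentwise difference (0 -> +1)."""
    n = states.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            s = np.sum(states[i] - states[j])
            out[i, j] = -1.0 if s < 0 else 1.0
    return out
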