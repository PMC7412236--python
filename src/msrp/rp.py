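"""Recurrence-plot construction: delay embedding, distance matrices, sign masks.

A univariate sequence ``s(1..L)`` is mapped into ``m``-dimensional phase
space with delay ``tau``; state ``i`` is the delayed subsequence

    x(i) = [s(i), s(i + tau), ..., s(i + (m-1) tau)],   i = 1..N,

with ``N = L - (m-1) tau``.  The (unthresholded) recurrence plot is the
pairwise distance matrix ``RP[i, j] = ||x(i) - x(j)||``.  Because every
norm is non-negative, a rising and a falling sequence can produce the very
same image; the sign mask

    S[i, j] = sign( sum(x(i) - x(j)) )      (+1 where the sum is zero)

restores the lost trend direction, and the signed recurrence plot is the
entrywise product ``S * RP``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .series import TimeSeries

__all__ = [
    "EmbedConfig",
    "PhaseStates",
    "RPImage",
    "SignMask",
    "EmbeddingError",
    "embed",
    "recurrence_matrix",
    "sign_mask",
    "signed_recurrence_matrix",
    "encode",
]

#: supported state-space norms -> the metric name scipy.spatial.distance uses
NORMS = {
    "l1": "cityblock",
    "l2": "euclidean",
    "l2sq": "sqeuclidean",
    "linf": "chebyshev",
}

#: default norm.  The field's worked examples print squared-L2 magnitudes
#: (the recurrence matrix of [1,2,3] at (m, tau) = (2, 1) is [[0,2],[2,0]]),
#: which plain L2 does not reproduce (it gives sqrt(2)); see docs/methods.md.
DEFAULT_NORM = "l2sq"


class EmbeddingError(ValueError):
    """Raised when a sequence is too short for the requested embedding."""


@dataclass(frozen=True)
class EmbedConfig:
    """Parameters governing recurrence-plot construction.

    Parameters
    ----------
    m
        Phase-space dimension (length of each delayed subsequence), >= 1.
    tau
        Embedding time delay (stride between subsequence components), >= 1.
    norm
        One of ``l1``, ``l2``, ``l2sq``, ``linf``.
    epsilon
        Recurrence threshold, required when ``binarize`` is true.
    binarize
        Apply the Heaviside step ``Theta(epsilon - d)`` to the distance
        matrix (classic thresholded recurrence plot).  Off by default:
        binarization discards texture and is usually omitted when the
        image feeds a convolutional classifier.
    """

    m: int = 2
    tau: int = 1
    norm: str = DEFAULT_NORM
    epsilon: float | None = None
    binarize: bool = False

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"tau must be an integer >= 1, got {self.tau}")
        if self.norm not in NORMS:
            raise ValueError(f"unknown norm {self.norm!r}; choose from {sorted(NORMS)}")
        if self.binarize and self.epsilon is None:
            raise ValueError("binarize=True requires epsilon (Heaviside threshold)")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")


@dataclass(frozen=True)
class PhaseStates:
    """Delay-embedded states: row ``i`` is the subsequence starting at i."""

    states: np.ndarray  # (N, m)

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def m(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class RPImage:
    """A recurrence-plot image plus the provenance of its construction.

    ``pixels`` is N x N.  Unsigned symmetric images are non-negative with a
    zero diagonal; signed images are antisymmetric wherever the
    state-difference sum is nonzero; asymmetric images carry the upper
    triangle of one half-sequence and the lower triangle of the other.
    """

    pixels: np.ndarray
    signed: bool = False
    asymmetric: bool = False
    m: int = 2
    tau: int = 1
    norm: str = DEFAULT_NORM
    source_length: int | None = None

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray) -> "RPImage":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class SignMask:
    """An N x N matrix of +/-1 trend signs (zero difference sums map to +1)."""

    mask: np.ndarray


def embed(series: TimeSeries, config: EmbedConfig) -> PhaseStates:
    """Delay-embed a series into phase space.

    Returns ``N = L - (m-1) tau`` states; raises :class:`EmbeddingError`
    when the series is shorter than ``(m-1) tau + 1``.
    """
    v = series.values
    L = v.size
    m, tau = config.m, config.tau
    n = L - (m - 1) * tau
    if n < 1:
        raise EmbeddingError(
            f"embedding infeasible: length L={L} < (m-1)*tau + 1 = "
            f"{(m - 1) * tau + 1} for m={m}, tau={tau}"
        )
    # (N, m) view: column k holds s(i + k*tau)
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return PhaseStates(states=v[idx])


def recurrence_matrix(states: PhaseStates, config: EmbedConfig) -> RPImage:
    """Unsigned recurrence plot: pairwise state distances (or recurrences).

    Without binarization the result is the symmetric distance matrix under
    ``config.norm`` with an exactly zero diagonal.  With ``binarize`` the
    Heaviside step is applied: entry 1 where ``d <= epsilon`` else 0 (the
    boundary ``d == epsilon`` counts as recurrent).
    """
    x = states.states
    if x.shape[0] < 1:
        raise ValueError("no states to compare")
    d = cdist(x, x, metric=NORMS[config.norm])
    np.fill_diagonal(d, 0.0)
    if config.binarize:
        if config.epsilon is None:
            raise ValueError("binarize=True requires epsilon")
        d = (d <= config.epsilon).astype(np.float64)
    return RPImage(
        pixels=d,
        signed=False,
        asymmetric=False,
        m=config.m,
        tau=config.tau,
        norm=config.norm,
        source_length=x.shape[0] + (config.m - 1) * config.tau,
    )


def sign_mask(states: PhaseStates) -> SignMask:
    """Trend-sign mask: sign of the summed componentwise state difference.

    ``mask[i, j] = sign(sum(x(i) - x(j)))``, with zero sums (including the
    diagonal) mapped to +1 so that distance magnitude is preserved where
    trends cancel.  Off-diagonal entries with nonzero sum are antisymmetric:
    ``mask[i, j] = -mask[j, i]``.
    """
    sums = states.states.sum(axis=1)
    diff = sums[:, None] - sums[None, :]
    mask = np.where(diff < 0.0, -1.0, 1.0)
    return SignMask(mask=mask)


def signed_recurrence_matrix(states: PhaseStates, config: EmbedConfig) -> RPImage:
    """Signed recurrence plot: the sign mask times the distance matrix.

    The absolute value equals the unsigned recurrence plot entrywise.  Not
    defined for binarized images (a thresholded recurrence has no magnitude
    for the sign to modulate).
    """
    if config.binarize:
        raise ValueError("signed RP undefined for binarized images")
    rp = recurrence_matrix(states, config)
    mask = sign_mask(states)
    return replace(rp, pixels=mask.mask * rp.pixels, signed=True)


def encode(series: TimeSeries, config: EmbedConfig, signed: bool = True) -> RPImage:
    """One-call encoder: delay-embed, build the RP, optionally apply signs."""
    states = embed(series, config)
    if signed:
        img = signed_recurrence_matrix(states, config)
    else:
        img = recurrence_matrix(states, config)
    return replace(img, source_length=len(series))
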