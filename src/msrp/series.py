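"""Univariate time series container and per-series normalization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """A single labeled univariate sequence.

    Parameters
    ----------
    values
        Amplitudes, length ``L >= 2``; all entries must be finite.
    label
        Optional class label (integer after dataset-level remapping).
    id
        Optional identifier, e.g. the source row of a benchmark file.
    """

    values: np.ndarray
    label: int | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError(f"expected a 1-d sequence, got shape {v.shape}")
        if v.size < 2:
            raise ValueError(f"series must have length >= 2, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def znormalize(series: TimeSeries, ddof: int = 0) -> TimeSeries:
    """Z-normalize a series to mean 0 and unit standard deviation.

    This is the UCR-archive convention applied per series before encoding.
    A constant series is centered to all zeros (its standard deviation is
    zero, so no rescaling is attempted).
    """
    v = series.values
    if v.max() == v.min():  # constant: center exactly, never rescale
        out = np.zeros_like(v)
    else:
        out = (v - v.mean()) / v.std(ddof=ddof)
    return TimeSeries(out, label=series.label, id=series.id)
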