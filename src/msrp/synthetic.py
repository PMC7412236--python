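"""Seeded synthetic datasets exercising the encoder's failure modes.

Four families, each emulating a regime the method was designed around:

* ``triangle_wave`` — periodic triangle waves with random phase, the
  classic illustration of how (m, tau) changes the granularity of a
  recurrence image.
* ``trend_pair`` — two classes of noisy sequences with opposite monotone
  tendencies (rising vs. falling).  Their *unsigned* recurrence plots are
  identical up to noise — the tendency-confusion problem — while the sign
  mask separates them; modeled on control-chart style data.
* ``multiclass`` — three classes differing in trend sign and local shape
  (rising trend, falling trend, oscillation).
* ``long`` — the trend pair stretched past 700 points to exercise the
  asymmetric encoding path.

Defaults (30 series per class, length 60, noise sd 0.2) are the conditions
used by the package's desk-scale classification experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Dataset
from .series import TimeSeries

__all__ = ["SyntheticSpec", "generate_synthetic", "generate_train_test"]

KINDS = ("triangle_wave", "trend_pair", "multiclass", "long")


@dataclass(frozen=True)
class SyntheticSpec:
    """What to generate: family, class size, length, noise level, seed."""

    kind: str = "trend_pair"
    n_per_class: int = 30
    length: int = 60
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        if self.length <= 0 or self.n_per_class <= 0:
            raise ValueError("length and n_per_class must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind == "long" and self.length <= 700:
            raise ValueError("kind='long' requires length > 700")


def _triangle(phase: np.ndarray) -> np.ndarray:
    """Unit triangle wave of period 1 evaluated at ``phase``."""
    frac = np.mod(phase, 1.0)
    return 2.0 * np.abs(2.0 * frac - 1.0) - 1.0


def _class_protos(spec: SyntheticSpec, rng: np.random.Generator):
    """Yield (label, base-signal factory) pairs for the requested family."""
    t = np.linspace(0.0, 1.0, spec.length)
    trend = np.linspace(-1.0, 1.0, spec.length)

    if spec.kind == "triangle_wave":
        # a few cycles; phase drawn fresh per series
        return [(0, lambda: _triangle(4.0 * t + rng.uniform()))]
    if spec.kind in ("trend_pair", "long"):
        return [(0, lambda: trend), (1, lambda: -trend)]
    # multiclass: opposite trends plus an oscillatory class
    return [
        (0, lambda: trend),
        (1, lambda: -trend),
        (2, lambda: np.sin(2.0 * np.pi * 3.0 * t)),
    ]


def generate_synthetic(spec: SyntheticSpec, split: str = "train") -> Dataset:
    """Generate one seeded, reproducible synthetic dataset."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    series: list[TimeSeries] = []
    for label, proto in _class_protos(spec, rng):
        for i in range(spec.n_per_class):
            base = proto()
            noise = rng.normal(0.0, spec.noise_sd, size=spec.length) if spec.noise_sd else 0.0
            series.append(
                TimeSeries(base + noise, label=label, id=f"{spec.kind}-{label}-{i}")
            )
    return Dataset(series=series, name=spec.kind, split=split)


def generate_train_test(spec: SyntheticSpec) -> tuple[Dataset, Dataset]:
    """Matched train/test pair: the test set uses an offset of the seed."""
    train = generate_synthetic(spec, split="train")
    test = generate_synthetic(replace(spec, seed=spec.seed + 10007), split="test")
    return train, test
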