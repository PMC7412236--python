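"""Multi-scale machinery: asymmetric RPs for long sequences, resizing,
scale grids, and validation-based scale selection.

Two devices extend the basic recurrence plot to realistic benchmark data:

* **Multi-scale grids.**  The embedding pair ``(m, tau)`` — conventionally
  ``(2, 1)`` for fine-grained texture or ``(3, 4)`` for coarser, overview
  structure — is varied together with the output image size, and the
  combination that minimizes validation error is selected.

* **Asymmetric reassembly.**  A recurrence plot is symmetric, so half the
  image is redundant.  For long sequences (above 700 points by default) the
  sequence is halved, each half encoded separately, and the strict upper
  triangle of the first half's image combined with the strict lower
  triangle of the second half's — one image of half the side length with no
  loss beyond the diagonal, greatly reducing the downsampling loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize as _skimage_resize

from .rp import EmbedConfig, EmbeddingError, RPImage, encode
from .series import TimeSeries, znormalize

__all__ = [
    "ScaleGrid",
    "ScaleChoice",
    "DEFAULT_SIZES",
    "LONG_THRESHOLD",
    "split_halves",
    "asymmetric_rp",
    "resize_image",
    "encode_series",
    "generate_scales",
    "encode_dataset",
    "select_scale",
]

#: candidate image side lengths searched at benchmark scale
DEFAULT_SIZES = (16, 48, 64, 80, 96, 112, 128)

#: sequence length above which the asymmetric construction is used
LONG_THRESHOLD = 700


@dataclass(frozen=True)
class ScaleGrid:
    """The candidate (m, tau) pairs and image sizes for scale search."""

    mt_pairs: tuple[tuple[int, int], ...] = ((2, 1), (3, 4))
    sizes: tuple[int, ...] = DEFAULT_SIZES
    signed: bool = True
    long_threshold: int = LONG_THRESHOLD
    norm: str = "l2sq"

    def __post_init__(self) -> None:
        if not self.mt_pairs or not self.sizes:
            raise ValueError("scale grid must have at least one (m, tau) pair and one size")
        if any(s < 2 for s in self.sizes):
            raise ValueError("image sizes must be >= 2")


@dataclass(frozen=True)
class ScaleChoice:
    """The validation-selected scale and the search trace that produced it."""

    m: int
    tau: int
    size: int
    validation_error: float
    #: (m, tau, size, validation error) for every candidate actually trained
    evaluations: tuple[tuple[int, int, int, float], ...] = ()

    @property
    def n_trainings(self) -> int:
        return len(self.evaluations)


def split_halves(series: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    """Halve a sequence into two pieces of equal length ceil(L/2).

    For odd ``L`` the two halves share the middle point, so both halves
    (and hence both half-RPs) have identical dimensions.
    """
    v = series.values
    h = (v.size + 1) // 2
    first = TimeSeries(v[:h], label=series.label, id=series.id)
    second = TimeSeries(v[v.size - h:], label=series.label, id=series.id)
    return first, second


def asymmetric_rp(series: TimeSeries, config: EmbedConfig, signed: bool = True) -> RPImage:
    """Encode a long sequence as one asymmetric image from its two halves.

    Each half is encoded exactly like a short sequence (including the sign
    mask when ``signed``); the result's strict upper triangle is the first
    half's strict upper triangle, the strict lower triangle is the second
    half's, and the diagonal is zero (both half-RPs have zero diagonals).
    """
    first, second = split_halves(series)
    img1 = encode(first, config, signed=signed)
    img2 = encode(second, config, signed=signed)
    combined = np.triu(img1.pixels, k=1) + np.tril(img2.pixels, k=-1)
    return RPImage(
        pixels=combined,
        signed=signed,
        asymmetric=True,
        m=config.m,
        tau=config.tau,
        norm=config.norm,
        source_length=len(series),
    )


def resize_image(image: RPImage, size: int) -> RPImage:
    """Resize an RP image to ``size x size`` by bilinear interpolation.

    Bilinear resampling on a transpose-symmetric grid is linear in the
    pixel values, so it preserves the symmetry of unsigned images and the
    antisymmetry of signed images (up to float rounding).  No anti-alias
    prefilter is applied: smoothing across the diagonal would bleed
    opposite-signed pixels into each other.
    """
    if size < 2:
        raise ValueError(f"target size must be >= 2, got {size}")
    if size == image.size:
        return image
    out = _skimage_resize(
        image.pixels,
        (size, size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return image.with_pixels(out)


def encode_series(
    series: TimeSeries,
    config: EmbedConfig,
    signed: bool = True,
    long_threshold: int = LONG_THRESHOLD,
) -> RPImage:
    """Encode one series, taking the asymmetric path when it is long.

    Sequences longer than ``long_threshold`` are halved and reassembled
    asymmetrically; everything else gets a plain (signed) RP.
    """
    if len(series) > long_threshold:
        return asymmetric_rp(series, config, signed=signed)
    return encode(series, config, signed=signed)


def generate_scales(series: TimeSeries, grid: ScaleGrid) -> list[RPImage]:
    """Encode one series at every (m, tau, size) combination of the grid.

    Images are ordered by m, then tau, then size.  Infeasible (m, tau)
    entries (sequence too short) are reported as warnings per entry and
    skipped rather than aborting the whole grid.
    """
    images: list[RPImage] = []
    for m, tau in sorted(grid.mt_pairs):
        config = EmbedConfig(m=m, tau=tau, norm=grid.norm)
        try:
            base = encode_series(series, config, signed=grid.signed,
                                 long_threshold=grid.long_threshold)
        except EmbeddingError as exc:
            warnings.warn(f"skipping (m={m}, tau={tau}): {exc}", stacklevel=2)
            continue
        for size in sorted(grid.sizes):
            images.append(resize_image(base, size))
    return images


def encode_dataset(
    dataset,
    config: EmbedConfig,
    size: int,
    signed: bool = True,
    long_threshold: int = LONG_THRESHOLD,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every series of a dataset at one scale.

    Per-series z-normalization is applied first by default (the UCR
    convention).  Returns ``(images, labels)`` with images of shape
    ``(n, size, size)``.
    """
    stack = np.empty((len(dataset.series), size, size), dtype=np.float64)
    labels = np.empty(len(dataset.series), dtype=np.int64)
    for i, s in enumerate(dataset.series):
        if normalize:
            s = znormalize(s)
        img = encode_series(s, config, signed=signed, long_threshold=long_threshold)
        stack[i] = resize_image(img, size).pixels
        labels[i] = -1 if s.label is None else s.label
    return stack, labels


def select_scale(
    train,
    grid: ScaleGrid,
    train_cfg=None,
    arch: str = "cnn",
    pilot_size: int = 64,
    val_fraction: float = 0.2,
    seed: int = 0,
    normalize: bool = True,
) -> ScaleChoice:
    """Pick (m, tau) and the image size by validation error, in two stages.

    Stage 1 fixes a pilot image size and trains one classifier per
    ``(m, tau)`` candidate; the pair with the lowest validation error wins.
    Stage 2 fixes that pair and searches the image sizes, reusing the pilot
    result, so the total number of trainings is
    ``len(mt_pairs) + len(sizes) - 1`` when the pilot size is in the grid.
    Ties break toward the smaller size and toward the earlier (m, tau)
    candidate (``(2, 1)`` before ``(3, 4)`` in the default grid).

    The validation set is a stratified hold-out of ``val_fraction`` of the
    training set, split with the given seed; a class that cannot appear on
    both sides raises a stratification error.
    """
    from sklearn.model_selection import train_test_split

    from .nn import NetworkSpec, TrainConfig, build_network, train_model, predict
    from .evaluation import error_rate

    if train_cfg is None:
        train_cfg = TrainConfig()
    labels = np.array([s.label for s in train.series])
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("scale selection needs at least 2 labeled classes")
    if counts.min() < 2:
        raise ValueError(
            "stratified split infeasible: every class needs >= 2 training samples"
        )
    idx = np.arange(labels.size)
    idx_tr, idx_val = train_test_split(
        idx, test_size=val_fraction, stratify=labels, random_state=seed
    )
    n_classes = classes.size

    def _candidate_error(m: int, tau: int, size: int) -> float:
        config = EmbedConfig(m=m, tau=tau, norm=grid.norm)
        images, y = encode_dataset(
            train, config, size, signed=grid.signed,
            long_threshold=grid.long_threshold, normalize=normalize,
        )
        spec = NetworkSpec(kind=arch, input_size=size, n_classes=n_classes)
        model = build_network(spec, seed=train_cfg.seed)
        train_model(model, images[idx_tr], y[idx_tr], train_cfg)
        return error_rate(predict(model, images[idx_val]), y[idx_val])

    evaluations: list[tuple[int, int, int, float]] = []
    # stage 1: pilot size fixed, search (m, tau)
    stage1: list[tuple[float, int, tuple[int, int]]] = []
    for order, (m, tau) in enumerate(grid.mt_pairs):
        err = _candidate_error(m, tau, pilot_size)
        evaluations.append((m, tau, pilot_size, err))
        stage1.append((err, order, (m, tau)))
    best_err, _, (best_m, best_tau) = min(stage1)

    # stage 2: (m, tau) fixed, search sizes; the pilot training is reused
    stage2: list[tuple[float, int]] = []
    if pilot_size in grid.sizes:
        stage2.append((best_err, pilot_size))
    for size in grid.sizes:
        if size == pilot_size:
            continue
        err = _candidate_error(best_m, best_tau, size)
        evaluations.append((best_m, best_tau, size, err))
        stage2.append((err, size))
    final_err, final_size = min(stage2)

    return ScaleChoice(
        m=best_m,
        tau=best_tau,
        size=final_size,
        validation_error=final_err,
        evaluations=tuple(evaluations),
    )
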