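"""Reading and writing UCR-style delimited text and encoded image stacks.

A UCR-archive-style file holds one labeled series per row: the class label
first, then the amplitudes, tab- or comma-separated; TRAIN and TEST live in
separate files and all series in a file share one length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .series import TimeSeries

__all__ = [
    "Dataset",
    "read_ucr",
    "write_ucr",
    "save_image_stack",
    "load_image_stack",
]


@dataclass
class Dataset:
    """A list of equal-length labeled series plus the label remapping."""

    series: list[TimeSeries]
    name: str = ""
    split: str = ""
    #: original label token -> contiguous class index
    label_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.series}
        if len(lengths) > 1:
            raise ValueError(
                f"unequal series lengths {sorted(lengths)}; "
                "variable-length datasets are not supported"
            )

    def __len__(self) -> int:
        return len(self.series)

    @property
    def length(self) -> int:
        return len(self.series[0]) if self.series else 0

    @property
    def n_classes(self) -> int:
        return len({s.label for s in self.series if s.label is not None})

    def labels(self) -> np.ndarray:
        return np.array([-1 if s.label is None else s.label for s in self.series])

    def values(self) -> np.ndarray:
        return np.vstack([s.values for s in self.series])


def _label_key(token: str):
    try:
        return (0, float(token))
    except ValueError:
        return (1, token)


def read_ucr(path: str | Path, name: str = "", split: str = "") -> Dataset:
    """Parse a UCR-style delimited text file into a :class:`Dataset`.

    The delimiter (tab or comma) is auto-detected from the first row.
    Labels are remapped to contiguous integers 0..K-1 (numeric tokens in
    numeric order), with the original tokens kept in ``label_map``.
    """
    path = Path(path)
    rows: list[tuple[str, np.ndarray]] = []
    with path.open() as fh:
        delim = None
        width = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if delim is None:
                delim = "\t" if "\t" in line else ","
            cells = line.split(delim)
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path.name}: inconsistent length at row {lineno} "
                    f"({len(cells)} cells, expected {width})"
                )
            try:
                values = np.array([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise ValueError(f"{path.name}: non-numeric cell at row {lineno}: {exc}")
            rows.append((cells[0], values))
    if not rows:
        raise ValueError(f"{path.name}: empty file")
    tokens = sorted({tok for tok, _ in rows}, key=_label_key)
    label_map = {tok: i for i, tok in enumerate(tokens)}
    series = [
        TimeSeries(values, label=label_map[tok], id=f"{path.stem}[{i}]")
        for i, (tok, values) in enumerate(rows)
    ]
    return Dataset(series=series, name=name or path.stem, split=split, label_map=label_map)


def write_ucr(dataset: Dataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a dataset back to delimited text (17 significant digits)."""
    inverse = {v: k for k, v in dataset.label_map.items()}
    with Path(path).open("w") as fh:
        for s in dataset.series:
            label = inverse.get(s.label, str(s.label if s.label is not None else 0))
            cells = [label] + [format(v, ".17g") for v in s.values]
            fh.write(delimiter.join(cells) + "\n")


def save_image_stack(
    path: str | Path,
    images: np.ndarray,
    labels: np.ndarray,
    meta: dict | None = None,
) -> None:
    """Store an encoded image stack (n, size, size) with labels and metadata."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=np.asarray(images))
        fh.create_dataset("labels", data=np.asarray(labels))
        for key, value in (meta or {}).items():
            fh.attrs[key] = value


def load_image_stack(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as fh:
        images = fh["images"][...]
        labels = fh["labels"][...]
        meta = dict(fh.attrs)
    return images, labels, meta
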