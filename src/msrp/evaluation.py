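"""Benchmark comparison metrics: error rate, win counts, mean ranks, MPCE.

Given a datasets x methods matrix of test error rates, a method is
summarized by:

* **win count** — the number of datasets on which its error equals the row
  minimum (all tied minima count as wins);
* **arithmetic / geometric mean rank** — per-dataset ranks 1..M assigned
  ascending by error, averaged arithmetically or as exp(mean log rank);
* **MPCE** — mean per-class error, the mean over datasets of
  error_k / C_k with C_k the dataset's class count, normalizing away the
  difficulty differences between few- and many-class problems.

Tied ranks take the minimum rank of the tie group by default; that is the
convention under which the packaged benchmark table's printed summary rows
reproduce (see docs/methods.md for the analysis).  The average-rank
convention is available via ``ties="average"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ResultTable",
    "error_rate",
    "win_count",
    "mean_rank",
    "mpce",
    "summarize",
]


@dataclass
class ResultTable:
    """A datasets x methods error-rate matrix with optional class counts."""

    errors: pd.DataFrame
    #: per-dataset class counts, indexed like ``errors`` (needed for MPCE)
    n_classes: pd.Series | None = None
    #: optional per-dataset metadata (e.g. the selected image scale)
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.errors.to_numpy()
        if vals.size == 0:
            raise ValueError("empty result table")
        if np.isnan(vals).any():
            raise ValueError("result table has missing cells")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("error rates must lie in [0, 1]")

    @property
    def dataset_names(self) -> list[str]:
        return list(self.errors.index)

    @property
    def method_names(self) -> list[str]:
        return list(self.errors.columns)

    def _column(self, method: str) -> np.ndarray:
        if method not in self.errors.columns:
            raise KeyError(f"unknown method {method!r}; have {self.method_names}")
        return self.errors[method].to_numpy()


def error_rate(predictions, labels) -> float:
    """Fraction of misclassified samples."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("cannot compute an error rate on empty input")
    if predictions.shape != labels.shape:
        raise ValueError(f"shape mismatch: {predictions.shape} vs {labels.shape}")
    return float(np.mean(predictions != labels))


def win_count(table: ResultTable, method: str) -> int:
    """Datasets on which the method attains the row-minimum error."""
    col = table._column(method)
    row_min = table.errors.to_numpy().min(axis=1)
    return int(np.sum(col == row_min))


def _rank_matrix(table: ResultTable, ties: str) -> np.ndarray:
    errs = table.errors.to_numpy()
    return np.vstack([rankdata(row, method=ties) for row in errs])


def mean_rank(table: ResultTable, method: str, kind: str = "arithmetic",
              ties: str = "min") -> float:
    """Mean per-dataset rank of a method (arithmetic or geometric)."""
    if kind not in ("arithmetic", "geometric"):
        raise ValueError("kind must be 'arithmetic' or 'geometric'")
    table._column(method)  # validate the method name
    j = table.method_names.index(method)
    ranks = _rank_matrix(table, ties)[:, j]
    if kind == "arithmetic":
        return float(ranks.mean())
    return float(np.exp(np.log(ranks).mean()))


def mpce(table: ResultTable, method: str) -> float:
    """Mean per-class error: average of error / class-count over datasets."""
    if table.n_classes is None:
        raise ValueError("MPCE needs per-dataset class counts")
    counts = table.n_classes.reindex(table.errors.index)
    if counts.isna().any():
        missing = list(counts.index[counts.isna()])
        raise ValueError(f"missing class counts for datasets: {missing}")
    col = table._column(method)
    return float(np.mean(col / counts.to_numpy()))


def summarize(table: ResultTable, ties: str = "min") -> pd.DataFrame:
    """Summary rows (wins, mean ranks, MPCE when available) per method."""
    rows: dict[str, list[float]] = {
        "win_num": [win_count(table, m) for m in table.method_names],
        "arithmetic_ranking": [
            mean_rank(table, m, "arithmetic", ties) for m in table.method_names
        ],
        "geometric_ranking": [
            mean_rank(table, m, "geometric", ties) for m in table.method_names
        ],
    }
    if table.n_classes is not None:
        rows["mpce"] = [mpce(table, m) for m in table.method_names]
    return pd.DataFrame(rows, index=table.method_names).T
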