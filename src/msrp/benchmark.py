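"""The packaged 45-dataset benchmark error-rate table.

``table2.tsv`` transcribes the published comparison of nine classifiers
over 45 UCR-archive datasets: per-dataset test error rates for RP-CNN,
ResNet, FCN, RP-FCN, HIVE-COTE, FCN-RCF, ALSTM-FCN, and the two MS-RP
variants, together with the image scale each dataset was encoded at
(image size, m, tau).  The summary rows printed alongside the original
table (win counts, arithmetic and geometric rankings) can be recomputed
from this matrix with :mod:`msrp.evaluation`.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .evaluation import ResultTable

__all__ = ["load_table2", "TABLE2_METHODS"]

TABLE2_METHODS = (
    "RP-CNN",
    "ResNet",
    "FCN",
    "RP-FCN",
    "HIVE-COTE",
    "FCN-RCF",
    "ALSTM-FCN",
    "MS-RP-ResNet",
    "MS-RP-FCN",
)

_SHA256 = "d6021ad7c0c8fc9c05b46d962c885ef45928a1df36f6b4d7d45813b5b5e4a6a8"


class FixtureCorruption(RuntimeError):
    """Raised when the packaged benchmark table fails its checksum."""


def load_table2() -> ResultTable:
    """Load the packaged benchmark table, verifying its checksum.

    Returns a :class:`~msrp.evaluation.ResultTable` whose ``meta`` frame
    carries the per-dataset encoding scale (``size``, ``m``, ``tau``).
    Per-dataset class counts are not part of the published table, so
    ``n_classes`` is ``None`` and MPCE requires user-supplied counts.
    """
    ref = resources.files("msrp") / "data" / "table2.tsv"
    text = ref.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _SHA256:
        raise FixtureCorruption(
            f"benchmark fixture checksum mismatch: {digest} != {_SHA256}"
        )
    frame = pd.read_csv(ref.open("r"), sep="\t", index_col="dataset")
    meta = frame[["size", "m", "tau"]]
    errors = frame[list(TABLE2_METHODS)].astype(float)
    return ResultTable(errors=errors, n_classes=None, meta=meta)
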