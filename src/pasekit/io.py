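"""Tab-separated I/O with deterministic float formatting.

All tables move between stages as TSV; floats are written with ``%.10g`` so
re-running with the same seed yields byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
                 lineterminator="\n")
    return path


def read_tsv(path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix_tsv(matrix: np.ndarray, labels, path) -> Path:
    frame = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    return write_tsv(frame, path)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
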