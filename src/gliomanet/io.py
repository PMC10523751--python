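"""Readers and writers for the package's text formats.

Expression matrices are TSV/CSV with samples as rows, the first column the
sample id and the header the feature names; an orientation flag accepts
genes-as-rows files and transposes. Labels are two-column TSV
(sample_id, class).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def read_expression(path, orientation: str = "samples", sep: str | None = None
                    ) -> pd.DataFrame:
    """Read an expression matrix; ``orientation`` is "samples" or "genes"."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes":
        df = df.T
    elif orientation != "samples":
        raise ValueError("orientation must be 'samples' or 'genes'")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate sample id(s): {list(dups)[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique()
        raise ValueError(f"duplicate feature name(s): {list(dups)[:5]}")
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric column(s): {list(bad)[:5]}")
    if df.isna().any().any():
        raise ValueError("missing values in expression matrix")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    """Write at 17 significant digits so text round-trips are lossless."""
    df.to_csv(path, sep="\t", index_label="sample_id",
              float_format="%.17g")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels file needs columns (sample_id, class)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="class")
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique()
        raise ValueError(f"duplicate sample id(s): {list(dups)[:5]}")
    return s


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "class": labels.to_numpy()}
                 ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
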