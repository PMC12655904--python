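"""Delimited-text I/O shared across the pipeline.

Dialect: comma-separated, UTF-8, header row, ligand id in the first
column, "." decimal separator.  Typographic minus signs (U+2212), which
appear in typeset tables, are normalized to ASCII hyphens on read.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "read_json",
    "write_json",
]

_MINUS = "−"


def read_table(path_or_text, index_col: int | None = 0) -> pd.DataFrame:
    """Read a delimited table; first column is the ligand id by default."""
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = str(path_or_text)
    text = text.replace(_MINUS, "-")
    return pd.read_csv(_io.StringIO(text), index_col=index_col, comment="#")


def write_table(
    df: pd.DataFrame, path, header_comment: str | None = None
) -> None:
    """Write a table with the ligand id as the first column.

    ``header_comment`` (without the leading ``#``) is prepended as a
    comment line, used to stamp outputs with the producing config hash.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, lineterminator="\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n",
        encoding="utf-8",
    )


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
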