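"""Canonical TSV writer used by every pipeline stage.

Output files carry a ``#``-prefixed metadata header (sorted keys, so the
same metadata always serialises identically) followed by a plain
tab-separated table. Floats are written with 6 significant digits by
default; ``round_digits`` switches to fixed decimals to mimic the
2-decimal presentation of published tables.
"""

from __future__ import annotations

import os

import pandas as pd


def write_tsv(
    df: pd.DataFrame,
    path: str | os.PathLike,
    meta: dict | None = None,
    index: bool = False,
    round_digits: int | None = None,
) -> None:
    float_format = f"%.{round_digits}f" if round_digits is not None else "%.6g"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(meta or {}):
            fh.write(f"# {key}: {(meta or {})[key]}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_tsv(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    """Read a file written by :func:`write_tsv`, skipping metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
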