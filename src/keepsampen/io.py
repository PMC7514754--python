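"""Readers and writers for one-value-per-row series files and result tables.

Series files are plain text with one sample per row (optionally one column of
a delimited table); missing points are written as the token ``NA``, the
convention of the statistical software most users of these signals already
have in their pipelines.  Values round-trip at full double precision (17
significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .core import TimeSeries
from .evaluation import ErrorRecord, records_to_frame

__all__ = ["SeriesDialect", "SeriesParseError", "read_series", "write_series", "write_records"]

_DELIMITERS = {"comma": ",", "tab": "\t", "whitespace": None}

DEFAULT_NA_TOKENS = frozenset({"NA", "NaN", "nan", ""})


class SeriesParseError(ValueError):
    """A token that is neither numeric nor a recognized NA token."""


@dataclass(frozen=True)
class SeriesDialect:
    """How to interpret a series file: delimiter, column (1-based), NA tokens."""

    delimiter: str = "whitespace"
    column: int = 1
    na_tokens: frozenset = DEFAULT_NA_TOKENS
    header: bool = False

    def __post_init__(self) -> None:
        if self.delimiter not in _DELIMITERS:
            raise ValueError(
                f"delimiter must be one of {sorted(_DELIMITERS)}, got {self.delimiter!r}"
            )
        if self.column < 1:
            raise ValueError(f"column must be >= 1, got {self.column}")
        if not self.na_tokens:
            raise ValueError("na_tokens must be non-empty")


def _split(line: str, delimiter: str) -> list[str]:
    sep = _DELIMITERS[delimiter]
    return line.split() if sep is None else [t.strip() for t in line.split(sep)]


def read_series(
    path: Union[str, Path], dialect: SeriesDialect = SeriesDialect()
) -> TimeSeries:
    """Read a series; numeric tokens become observed values, NA tokens missing."""
    path = Path(path)
    values: list[float] = []
    mask: list[bool] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if dialect.header and lineno == 1:
                continue
            if not line.strip():
                continue
            tokens = _split(line, dialect.delimiter)
            if dialect.column > len(tokens):
                raise SeriesParseError(
                    f"{path}:{lineno}: only {len(tokens)} column(s), "
                    f"need column {dialect.column}"
                )
            token = tokens[dialect.column - 1]
            if token in dialect.na_tokens:
                values.append(np.nan)
                mask.append(False)
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise SeriesParseError(
                    f"{path}:{lineno}: cannot parse {token!r} as a number "
                    f"(not an NA token either)"
                ) from None
            mask.append(True)
    if not values:
        raise SeriesParseError(f"{path}: no data rows")
    return TimeSeries(values=np.asarray(values), mask=np.asarray(mask, dtype=bool))


def write_series(
    series: TimeSeries, path: Union[str, Path], na_token: str = "NA"
) -> None:
    """Write one value per row; missing points as ``na_token``.

    Round-trip safe: reading the file back reproduces the mask exactly and
    the values to full double precision.
    """
    if series.n == 0:
        raise ValueError("refusing to write an empty series")
    path = Path(path)
    with path.open("w") as fh:
        for value, observed in zip(series.values, series.mask):
            fh.write(f"{value:.17g}\n" if observed else f"{na_token}\n")


def write_records(records: Iterable[ErrorRecord], path: Union[str, Path]) -> None:
    """Write evaluation records as a long-format CSV, stable-ordered."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    """Read an evaluation-results CSV back into a table."""
    return pd.read_csv(path)
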