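"""Reading raw per-droplet amplitude exports and writing quantification tables.

Droplet readers export one comma-separated file per well with one row per
accepted droplet and one end-point fluorescence amplitude per channel.
Columns are located by header token match (not position) because column
order varies between software versions; extra columns such as a cluster
label are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DropletSet",
    "AmplitudeFormatError",
    "AmplitudeParseError",
    "EmptyInputError",
    "read_amplitude_export",
    "write_results_table",
    "read_results_table",
]


class AmplitudeFormatError(ValueError):
    """The export's header does not identify the two amplitude columns."""


class AmplitudeParseError(ValueError):
    """An amplitude cell could not be parsed as a number."""


class EmptyInputError(ValueError):
    """The export contains a header but no droplet rows."""


@dataclass(frozen=True)
class DropletSet:
    """Two-channel fluorescence amplitudes for the accepted droplets of one well.

    Channel 1 is plotted vertically and channel 2 horizontally in the usual
    2-D amplitude chart. Both arrays are parallel: entry *i* is droplet *i*.
    """

    well_id: str
    ch1: np.ndarray
    ch2: np.ndarray

    def __post_init__(self) -> None:
        ch1 = np.asarray(self.ch1, dtype=float)
        ch2 = np.asarray(self.ch2, dtype=float)
        if ch1.ndim != 1 or ch2.ndim != 1:
            raise ValueError("amplitude arrays must be one-dimensional")
        if ch1.shape != ch2.shape:
            raise ValueError(
                f"channel lengths differ: ch1 has {ch1.size}, ch2 has {ch2.size}"
            )
        if ch1.size and not (np.isfinite(ch1).all() and np.isfinite(ch2).all()):
            raise ValueError("amplitudes must be finite")
        object.__setattr__(self, "ch1", ch1)
        object.__setattr__(self, "ch2", ch2)

    @property
    def n_accepted(self) -> int:
        return int(self.ch1.size)


def _find_column(columns: Sequence[str], tokens: Iterable[str]) -> str | None:
    """Return the first column whose header contains every token (case-insensitive)."""
    toks = [t.lower() for t in tokens]
    for col in columns:
        low = str(col).lower()
        if all(t in low for t in toks):
            return col
    return None


def read_amplitude_export(
    stream: IO[str] | str,
    well_id: str = "well",
    *,
    ch1_tokens: Sequence[str] = ("ch1", "amplitude"),
    ch2_tokens: Sequence[str] = ("ch2", "amplitude"),
) -> DropletSet:
    """Parse a raw comma-separated droplet amplitude export.

    Parameters
    ----------
    stream
        Open text stream or path of a CSV file with a header row.
    well_id
        Label attached to the returned :class:`DropletSet`.
    ch1_tokens, ch2_tokens
        Header tokens that must all occur (case-insensitively) in the
        channel-1 / channel-2 amplitude column names. The defaults match
        headers such as ``"Ch1 Amplitude"``; they are configurable because
        instrument export header names are not standardised.
    """
    frame = pd.read_csv(stream, dtype=str, skipinitialspace=True)
    c1 = _find_column(frame.columns, ch1_tokens)
    c2 = _find_column(frame.columns, ch2_tokens)
    if c1 is None or c2 is None:
        raise AmplitudeFormatError(
            "could not identify amplitude columns "
            f"(looked for tokens {list(ch1_tokens)} and {list(ch2_tokens)}) "
            f"in header {list(frame.columns)}"
        )
    if len(frame) == 0:
        raise EmptyInputError(f"well {well_id!r}: export contains no droplet rows")
    out = {}
    for name, col in (("ch1", c1), ("ch2", c2)):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            row = int(bad[0]) + 2
            raise AmplitudeParseError(
                f"well {well_id!r}: non-numeric value {frame[col].iloc[int(bad[0])]!r} "
                f"in column {col!r} at line {row}"
            )
        out[name] = values.to_numpy(dtype=float)
    return DropletSet(well_id=well_id, ch1=out["ch1"], ch2=out["ch2"])


_RESULT_COLUMNS = (
    "well",
    "target",
    "positives",
    "total",
    "p_hat",
    "lambda",
    "copies_per_uL",
    "copies_per_reaction",
    "ci_low",
    "ci_high",
    "detected",
)


def _fmt(x: float, digits: int) -> str:
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.{digits}g}"


def write_results_table(results, stream: IO[str], *, digits: int = 4) -> None:
    """Write quantification results as a tab-delimited long-format table.

    One row per (well, target). Integer fields are written exactly; floating
    fields are rendered with ``digits`` significant digits (default 4).

    Parameters
    ----------
    results
        Non-empty sequence of :class:`~ddplex.quantify.TargetResult`.
    stream
        Writable text sink.
    """
    results = list(results)
    if not results:
        raise ValueError("results list is empty")
    stream.write("\t".join(_RESULT_COLUMNS) + "\n")
    for r in results:
        row = (
            r.well_id,
            r.target_name,
            str(r.positives),
            str(r.total),
            _fmt(r.p_hat, digits),
            _fmt(r.lambda_, digits),
            _fmt(r.copies_per_uL, digits),
            _fmt(r.copies_per_reaction, digits),
            _fmt(r.ci_low, digits),
            _fmt(r.ci_high, digits),
            "yes" if r.detected else "no",
        )
        stream.write("\t".join(row) + "\n")


def read_results_table(stream: IO[str] | str) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    frame = pd.read_csv(stream, sep="\t")
    missing = set(_RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise AmplitudeFormatError(f"results table missing columns: {sorted(missing)}")
    return frame
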