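"""Fraction-collector plate geometry.

Maps chromatographic retention time to fraction index and fraction index
to 96-well plate address, for the microplate fractionation format used in
high-throughput effect-directed analysis (e.g. 18 s fractions collected
into 80 wells of a 96-well plate over a 24 min window).

Conventions
-----------
* Fraction indices are 1-based.
* Fraction time windows are half-open ``[rt_start, rt_end)`` so a boundary
  retention time maps to exactly one fraction.
* Retention times are seconds internally; :func:`minutes` converts.
* The fill order of the collector is configurable because instruments
  differ; the default is column-major starting at A1 (A1, B1, ... H1,
  A2, ...).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import pandas as pd

from ._errors import HtedaError

FillOrder = Literal[
    "column_major", "row_major", "serpentine_by_column", "serpentine_by_row"
]

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"
_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


def minutes(t_min: float) -> float:
    """Convert a retention time in minutes to seconds."""
    return float(t_min) * 60.0


@dataclass(frozen=True, order=True)
class WellAddress:
    """A microplate well, e.g. B8 = row B, column 8."""

    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in _ROW_LETTERS:
            raise HtedaError(f"invalid plate row {self.row!r}")
        if not 1 <= self.col <= 24:
            raise HtedaError(f"invalid plate column {self.col}")

    @classmethod
    def parse(cls, label: str) -> "WellAddress":
        m = _WELL_RE.match(label.strip().upper())
        if not m:
            raise HtedaError(f"cannot parse well label {label!r}")
        return cls(m.group(1), int(m.group(2)))

    @property
    def row_index(self) -> int:
        """0-based row index (A = 0)."""
        return _ROW_LETTERS.index(self.row)

    def __str__(self) -> str:
        return f"{self.row}{self.col}"


def n_fractions_for(duration_s: float, interval_s: float) -> int:
    """Number of complete fractions collected in ``duration_s``.

    A partial final interval is discarded: 24 min at 18 s/fraction
    gives exactly 80 fractions.
    """
    if duration_s <= 0 or interval_s <= 0:
        raise HtedaError(
            f"duration and interval must be positive, got "
            f"({duration_s}, {interval_s})"
        )
    return int(math.floor(duration_s / interval_s + 1e-12))


@dataclass(frozen=True)
class FractionScheme:
    """Fraction-collection scheme linking retention time to plate wells.

    Parameters
    ----------
    interval_s : collection time per fraction, seconds (> 0).
    n_fractions : number of fractions collected (1 .. rows*cols).
    start_time_s : retention time at which collection starts, seconds.
    plate_rows, plate_cols : plate format (default 8 x 12 = 96-well).
    fill_order : order in which wells are filled.
    start_well : first well filled (offset into the fill order).
    """

    interval_s: float
    n_fractions: int
    start_time_s: float = 0.0
    plate_rows: int = 8
    plate_cols: int = 12
    fill_order: FillOrder = "column_major"
    start_well: WellAddress = field(default_factory=lambda: WellAddress("A", 1))

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise HtedaError("interval_s must be > 0")
        if self.start_time_s < 0:
            raise HtedaError("start_time_s must be >= 0")
        if not 1 <= self.n_fractions <= self.plate_rows * self.plate_cols:
            raise HtedaError(
                f"n_fractions must be in [1, {self.plate_rows * self.plate_cols}]"
            )
        if self.start_well.row_index >= self.plate_rows or (
            self.start_well.col > self.plate_cols
        ):
            raise HtedaError("start_well outside plate")
        if self._start_offset() + self.n_fractions > self.plate_rows * self.plate_cols:
            raise HtedaError(
                "scheme overflows the plate: start_well offset plus "
                "n_fractions exceeds the well count"
            )

    # -- well enumeration ------------------------------------------------

    def _well_sequence(self) -> list[WellAddress]:
        rows, cols = self.plate_rows, self.plate_cols
        seq: list[WellAddress] = []
        if self.fill_order in ("column_major", "serpentine_by_column"):
            for c in range(1, cols + 1):
                r_iter: Iterator[int] = iter(range(rows))
                if self.fill_order == "serpentine_by_column" and c % 2 == 0:
                    r_iter = iter(range(rows - 1, -1, -1))
                for r in r_iter:
                    seq.append(WellAddress(_ROW_LETTERS[r], c))
        else:
            for r in range(rows):
                c_iter: Iterator[int] = iter(range(1, cols + 1))
                if self.fill_order == "serpentine_by_row" and r % 2 == 1:
                    c_iter = iter(range(cols, 0, -1))
                for c in c_iter:
                    seq.append(WellAddress(_ROW_LETTERS[r], c))
        return seq

    def _start_offset(self) -> int:
        return self._well_sequence().index(self.start_well)

    # -- mappings --------------------------------------------------------

    def fraction_to_well(self, index: int) -> WellAddress:
        """Well receiving fraction ``index`` (1-based)."""
        if not 1 <= index <= self.n_fractions:
            raise HtedaError(
                f"fraction index {index} outside [1, {self.n_fractions}]"
            )
        return self._well_sequence()[self._start_offset() + index - 1]

    def well_to_fraction(self, well: WellAddress | str) -> Optional[int]:
        """Inverse of :meth:`fraction_to_well`; None for wells not used."""
        if isinstance(well, str):
            well = WellAddress.parse(well)
        pos = self._well_sequence().index(well) - self._start_offset()
        idx = pos + 1
        return idx if 1 <= idx <= self.n_fractions else None

    def rt_to_fraction(self, rt_s: float) -> Optional[int]:
        """Fraction collecting at retention time ``rt_s`` (seconds).

        Returns None outside the collection window. Windows are
        half-open, so an RT exactly on a boundary belongs to the later
        fraction.
        """
        idx = 1 + math.floor((rt_s - self.start_time_s) / self.interval_s)
        return int(idx) if 1 <= idx <= self.n_fractions else None

    def fraction_window(self, index: int) -> tuple[float, float]:
        """Half-open RT window ``[rt_start, rt_end)`` of a fraction, seconds."""
        if not 1 <= index <= self.n_fractions:
            raise HtedaError(
                f"fraction index {index} outside [1, {self.n_fractions}]"
            )
        start = self.start_time_s + (index - 1) * self.interval_s
        return (start, start + self.interval_s)

    @property
    def collection_window(self) -> tuple[float, float]:
        return (
            self.start_time_s,
            self.start_time_s + self.n_fractions * self.interval_s,
        )

    # -- export ----------------------------------------------------------

    def plate_map(self) -> pd.DataFrame:
        """Plate map with columns fraction_index, well, rt_start_s, rt_end_s."""
        rows = []
        for i in range(1, self.n_fractions + 1):
            s, e = self.fraction_window(i)
            rows.append(
                {
                    "fraction_index": i,
                    "well": str(self.fraction_to_well(i)),
                    "rt_start_s": s,
                    "rt_end_s": e,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FractionRecord:
    """One collected fraction: index, RT window and destination well."""

    index: int
    rt_start_s: float
    rt_end_s: float
    well: WellAddress


def fraction_records(scheme: FractionScheme) -> list[FractionRecord]:
    return [
        FractionRecord(i, *scheme.fraction_window(i), scheme.fraction_to_well(i))
        for i in range(1, scheme.n_fractions + 1)
    ]
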