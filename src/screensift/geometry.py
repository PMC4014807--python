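"""Microplate geometry and well-label handling.

Well labels follow the plate-map convention: a row letter (A..P on a
384-well plate, spreadsheet-style double letters beyond Z) followed by a
column number. Labels are normalized to a zero-padded form ("A1" -> "A01")
so that lexicographic order equals plate order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_WELL_RE = re.compile(r"^([A-Za-z]+)\s*0*(\d+)$")


def _row_index(letters: str) -> int:
    """Spreadsheet-style letters to 0-based row index (A=0, ..., Z=25, AA=26)."""
    idx = 0
    for ch in letters.upper():
        if not "A" <= ch <= "Z":
            raise ValueError(f"invalid row letters {letters!r}")
        idx = idx * 26 + (ord(ch) - ord("A") + 1)
    return idx - 1


def _row_letters(idx: int) -> str:
    if idx < 0:
        raise ValueError("row index must be >= 0")
    letters = ""
    idx += 1
    while idx:
        idx, rem = divmod(idx - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


@dataclass(frozen=True)
class PlateGeometry:
    """Rectangular plate layout; default is a 384-well plate (16 x 24)."""

    n_rows: int = 16
    n_cols: int = 24

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate geometry must have >= 1 row and column")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def _col_width(self) -> int:
        return max(2, len(str(self.n_cols)))

    def parse_well(self, label: str) -> tuple[int, int]:
        """Parse a well label into 0-based (row, column) indices."""
        m = _WELL_RE.match(str(label).strip())
        if m is None:
            raise ValueError(f"malformed well label {label!r}")
        row = _row_index(m.group(1))
        col = int(m.group(2)) - 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"well {label!r} outside {self.n_rows}x{self.n_cols} plate"
            )
        return row, col

    def format_well(self, row: int, col: int) -> str:
        """0-based (row, column) to normalized label, e.g. (0, 0) -> 'A01'."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"({row}, {col}) outside {self.n_rows}x{self.n_cols} plate")
        return f"{_row_letters(row)}{col + 1:0{self._col_width}d}"

    def normalize_well(self, label: str) -> str:
        return self.format_well(*self.parse_well(label))

    def all_wells(self) -> list[str]:
        """All well labels in row-major order."""
        return [
            self.format_well(i, j)
            for i in range(self.n_rows)
            for j in range(self.n_cols)
        ]


GEOMETRY_384 = PlateGeometry(16, 24)
GEOMETRY_96 = PlateGeometry(8, 12)
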