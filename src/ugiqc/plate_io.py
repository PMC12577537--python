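"""96- and 384-well plate models, quadrant reformatting, and plate-shaped I/O.

Reformatting follows the standard interleaved-quadrant convention for
stamping four 96-well plates into one 384: source plate k in {1,2,3,4},
well (r, c) (1-based), lands in 384 well
(2r - 1 + (k-1)//2, 2c - 1 + (k-1)%2), so plate 1 fills the odd-row/odd-
column quadrant, plate 2 odd/even, plate 3 even/odd, plate 4 even/even.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateMap",
    "WellAddress",
    "format_well",
    "heatmap_matrix",
    "invert_384_to_96",
    "parse_well",
    "reformat_96_to_384",
]

PLATE_SHAPES = {96: (8, 12), 384: (16, 24)}
_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """1-based (row, column); row 1 = 'A'."""

    row: int
    column: int

    def text(self) -> str:
        return f"{chr(ord('A') + self.row - 1)}{self.column}"


def _check_bounds(addr: WellAddress, plate_format: int) -> WellAddress:
    nrow, ncol = PLATE_SHAPES[plate_format]
    if not (1 <= addr.row <= nrow and 1 <= addr.column <= ncol):
        raise ValueError(
            f"well {addr.text()} out of bounds for {plate_format}-well format "
            f"(rows A-{chr(ord('A') + nrow - 1)}, columns 1-{ncol})"
        )
    return addr


def parse_well(text: str, plate_format: int = 96) -> WellAddress:
    """Parse 'A1'..'P24' into a bounds-checked address."""
    m = _WELL_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparsable well address: {text!r}")
    addr = WellAddress(row=ord(m.group(1).upper()) - ord("A") + 1,
                       column=int(m.group(2)))
    return _check_bounds(addr, plate_format)


def format_well(addr: WellAddress) -> str:
    return addr.text()


@dataclass
class PlateMap:
    """Assignment of compound ids to wells of one plate."""

    plate_id: str
    format: int  # 96 or 384
    wells: dict[WellAddress, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.format not in PLATE_SHAPES:
            raise ValueError(f"unsupported plate format: {self.format}")
        for addr in self.wells:
            _check_bounds(addr, self.format)

    def set(self, well: str | WellAddress, compound_id: str) -> None:
        addr = parse_well(well, self.format) if isinstance(well, str) else well
        self.wells[_check_bounds(addr, self.format)] = compound_id

    def get(self, well: str | WellAddress) -> str | None:
        addr = parse_well(well, self.format) if isinstance(well, str) else well
        return self.wells.get(addr)

    @property
    def compound_ids(self) -> list[str]:
        return [self.wells[a] for a in sorted(self.wells)]


def reformat_96_to_384(
    sources: list[PlateMap], plate_id: str = "combined384"
) -> PlateMap:
    """Stamp 1-4 source 96-well plates into one 384-well plate."""
    if not 1 <= len(sources) <= 4:
        raise ValueError(f"reformatting accepts 1-4 source plates, got {len(sources)}")
    dest = PlateMap(plate_id=plate_id, format=384)
    for k, src in enumerate(sources, start=1):
        if src.format != 96:
            raise ValueError(f"source plate {src.plate_id} is not 96-well")
        for addr, cid in src.wells.items():
            target = WellAddress(
                row=2 * addr.row - 1 + (k - 1) // 2,
                column=2 * addr.column - 1 + (k - 1) % 2,
            )
            dest.wells[target] = cid
    return dest


def invert_384_to_96(
    dest: PlateMap, source_ids: list[str] | None = None
) -> list[PlateMap]:
    """Exact inverse of :func:`reformat_96_to_384` (four 96-well plates)."""
    if dest.format != 384:
        raise ValueError("inversion expects a 384-well plate")
    ids = source_ids or [f"{dest.plate_id}_q{k}" for k in range(1, 5)]
    sources = [PlateMap(plate_id=i, format=96) for i in ids]
    for addr, cid in dest.wells.items():
        k = 2 * ((addr.row - 1) % 2) + (addr.column - 1) % 2  # 0..3
        src_addr = WellAddress(row=(addr.row + 1) // 2, column=(addr.column + 1) // 2)
        sources[k].wells[src_addr] = cid
    return sources


def heatmap_matrix(
    plate: PlateMap, values: dict[str, float] | pd.Series
) -> np.ndarray:
    """Plate-shaped grid of per-compound values; empty wells are NaN.

    Values supplied for compounds absent from the plate trigger a warning,
    not an error.
    """
    nrow, ncol = PLATE_SHAPES[plate.format]
    grid = np.full((nrow, ncol), np.nan)
    values = dict(values)
    on_plate = set(plate.wells.values())
    orphans = sorted(set(values) - on_plate)
    if orphans:
        warnings.warn(
            f"values supplied for compounds absent from plate "
            f"{plate.plate_id}: {orphans[:5]}{'...' if len(orphans) > 5 else ''}",
            stacklevel=2,
        )
    for addr, cid in plate.wells.items():
        if cid in values:
            grid[addr.row - 1, addr.column - 1] = values[cid]
    return grid


# ---------------------------------------------------------------------------
# CSV dialects: long form (plate_id, well, compound_id) and grid form

def write_plate_csv(plate: PlateMap, path) -> None:
    rows = [
        {"plate_id": plate.plate_id, "well": addr.text(), "compound_id": cid}
        for addr, cid in sorted(plate.wells.items())
    ]
    pd.DataFrame(rows, columns=["plate_id", "well", "compound_id"]).to_csv(
        path, index=False
    )


def read_plate_csv(path, plate_format: int) -> list[PlateMap]:
    df = pd.read_csv(path)
    plates = []
    for pid, grp in df.groupby("plate_id", sort=True):
        plate = PlateMap(plate_id=str(pid), format=plate_format)
        for r in grp.itertuples(index=False):
            plate.set(str(r.well), str(r.compound_id))
        plates.append(plate)
    return plates


def write_grid_csv(grid: np.ndarray, path, plate_format: int) -> None:
    nrow, ncol = PLATE_SHAPES[plate_format]
    if grid.shape != (nrow, ncol):
        raise ValueError(f"grid shape {grid.shape} does not match format {plate_format}")
    df = pd.DataFrame(
        grid,
        index=[chr(ord("A") + i) for i in range(nrow)],
        columns=[str(c) for c in range(1, ncol + 1)],
    )
    df.to_csv(path, index_label="row")


def read_grid_csv(path) -> np.ndarray:
    return pd.read_csv(path, index_col="row").to_numpy(dtype=float)
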