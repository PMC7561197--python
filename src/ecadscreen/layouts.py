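"""384-well plate layouts and well-coordinate conversion.

Wells are named as printed on plates: letter row A-P, 1-based column 1-24,
zero-padded ("A01" ... "P24"). Internally everything is 0-based (row, col).

Two named layouts mirror the screening design. The primary (SMARTpool)
layout carries 16 mock, 6 siCDH1, 6 siZEB1 and 6 siPLK1 control wells per
plate; the deconvolution layout carries 31 mock, 13 siCDH1, 13 siZEB1 and
4 siPLK1. Controls are confined to the declared control columns (the two
inner edge columns 2/23 plus the outer edge columns for the overflow);
sample wells fill columns 3-22 row-major.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import LayoutError

N_ROWS = 16
N_COLS = 24
ROWS = "ABCDEFGHIJKLMNOP"

ROLE_SAMPLE = "sample"
ROLE_MOCK = "mock"
ROLE_SICDH1 = "siCDH1"
ROLE_SIZEB1 = "siZEB1"
ROLE_SIPLK1 = "siPLK1"
ROLE_EMPTY = "empty"
ROLES = (ROLE_SAMPLE, ROLE_MOCK, ROLE_SICDH1, ROLE_SIZEB1, ROLE_SIPLK1, ROLE_EMPTY)
CONTROL_ROLES = (ROLE_MOCK, ROLE_SICDH1, ROLE_SIZEB1, ROLE_SIPLK1)

#: control-role well totals per plate for the two named layouts
PRIMARY_CONTROL_COUNTS = {ROLE_MOCK: 16, ROLE_SICDH1: 6, ROLE_SIZEB1: 6, ROLE_SIPLK1: 6}
DECONV_CONTROL_COUNTS = {ROLE_MOCK: 31, ROLE_SICDH1: 13, ROLE_SIZEB1: 13, ROLE_SIPLK1: 4}

SAMPLE_COLUMNS = tuple(range(3, 23))  # 1-based columns 3..22
CONTROL_COLUMNS = (1, 2, 23, 24)

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate-printed name, e.g. (0, 0) -> 'A01'."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise LayoutError(f"well index out of range: ({row}, {col})")
    return f"{ROWS[row]}{col + 1:02d}"


def well_index(name: str) -> tuple[int, int]:
    """Plate-printed name -> 0-based (row, col); accepts 'A1' and 'A01'."""
    m = _WELL_RE.match(str(name).strip().upper())
    if not m:
        raise LayoutError(f"not a valid 384-well position: {name!r}")
    row = ROWS.index(m.group(1))
    col = int(m.group(2)) - 1
    if not (0 <= col < N_COLS):
        raise LayoutError(f"column out of range in well {name!r}")
    return row, col


@dataclass(frozen=True)
class WellSpec:
    """Identity of one layout position."""

    role: str
    gene_symbol: str = ""
    duplex_index: int = 0  # 0 = SMARTpool, 1-4 = individual duplex

    def __post_init__(self):
        if self.role not in ROLES:
            raise LayoutError(f"unknown role {self.role!r}")
        if self.duplex_index not in (0, 1, 2, 3, 4):
            raise LayoutError(f"duplex_index must be 0-4, got {self.duplex_index}")


@dataclass(frozen=True)
class PlateLayout:
    """One 384-well plate map: position -> role/gene/duplex."""

    plate_id: str
    wells: Mapping[str, WellSpec]
    control_columns: tuple[int, ...] = CONTROL_COLUMNS

    def __post_init__(self):
        if len(self.wells) != N_ROWS * N_COLS:
            raise LayoutError(
                f"layout {self.plate_id!r} has {len(self.wells)} wells, expected 384"
            )
        for name, spec in self.wells.items():
            row, col = well_index(name)  # validates the name
            if spec.role in CONTROL_ROLES and (col + 1) not in self.control_columns:
                raise LayoutError(
                    f"control well {name} ({spec.role}) outside declared control "
                    f"columns {self.control_columns}"
                )

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for spec in self.wells.values():
            counts[spec.role] = counts.get(spec.role, 0) + 1
        return counts

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, s in self.wells.items() if s.role == role)

    @property
    def sample_wells(self) -> list[str]:
        return self.wells_with_role(ROLE_SAMPLE)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well": w,
                "role": s.role,
                "gene_symbol": s.gene_symbol,
                "duplex_index": s.duplex_index,
            }
            for w, s in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows)


def _control_block(counts: dict[str, int]) -> list[str]:
    """Flatten control roles into a deterministic placement order."""
    order = []
    for role in (ROLE_MOCK, ROLE_SICDH1, ROLE_SIZEB1, ROLE_SIPLK1):
        order.extend([role] * counts[role])
    return order


def _place_controls(counts: dict[str, int]) -> dict[str, WellSpec]:
    """Distribute control roles over the control columns, inner columns first.

    Columns 2 and 23 fill top-to-bottom first (the historical control
    columns); any overflow wraps onto columns 1 and 24. Unused control-column
    positions become 'empty'.
    """
    slots: list[str] = []
    for col in (2, 23, 1, 24):
        for row in range(N_ROWS):
            slots.append(well_name(row, col - 1))
    block = _control_block(counts)
    if len(block) > len(slots):
        raise LayoutError("more control wells than control-column positions")
    placed = {}
    # interleave the two inner columns so each carries half of every role
    inner = slots[: 2 * N_ROWS]
    interleaved = [w for pair in zip(inner[:N_ROWS], inner[N_ROWS:]) for w in pair]
    slots = interleaved + slots[2 * N_ROWS:]
    for well, role in zip(slots, block):
        placed[well] = WellSpec(role=role, gene_symbol=role.replace("si", "") if role.startswith("si") else "")
    for well in slots[len(block):]:
        placed[well] = WellSpec(role=ROLE_EMPTY)
    return placed


def primary_layout(plate_id: str, genes: Iterable[str]) -> PlateLayout:
    """SMARTpool-screen plate: one gene per sample well (duplex_index 0).

    ``genes`` fills columns 3-22 row-major; at most 320 genes per plate.
    """
    wells = _place_controls(PRIMARY_CONTROL_COUNTS)
    genes = list(genes)
    sample_slots = [
        well_name(row, col - 1) for row in range(N_ROWS) for col in SAMPLE_COLUMNS
    ]
    if len(genes) > len(sample_slots):
        raise LayoutError(
            f"{len(genes)} genes exceed the {len(sample_slots)} sample wells of one plate"
        )
    for well, gene in zip(sample_slots, genes):
        wells[well] = WellSpec(role=ROLE_SAMPLE, gene_symbol=gene, duplex_index=0)
    for well in sample_slots[len(genes):]:
        wells[well] = WellSpec(role=ROLE_EMPTY)
    return PlateLayout(plate_id=plate_id, wells=wells)


def deconvolution_layout(
    plate_id: str, gene_duplex_wells: Iterable[tuple[str, int]]
) -> PlateLayout:
    """Deconvolution plate: each sample well carries (gene, duplex 1-4).

    ``gene_duplex_wells`` lists one entry per well (a duplex replicated over
    several wells appears several times); fills columns 3-22 row-major.
    """
    wells = _place_controls(DECONV_CONTROL_COUNTS)
    entries = list(gene_duplex_wells)
    sample_slots = [
        well_name(row, col - 1) for row in range(N_ROWS) for col in SAMPLE_COLUMNS
    ]
    if len(entries) > len(sample_slots):
        raise LayoutError(
            f"{len(entries)} duplex wells exceed the {len(sample_slots)} sample wells"
        )
    for well, (gene, duplex) in zip(sample_slots, entries):
        if duplex not in (1, 2, 3, 4):
            raise LayoutError(f"deconvolution duplex_index must be 1-4, got {duplex}")
        wells[well] = WellSpec(role=ROLE_SAMPLE, gene_symbol=gene, duplex_index=duplex)
    for well in sample_slots[len(entries):]:
        wells[well] = WellSpec(role=ROLE_EMPTY)
    return PlateLayout(plate_id=plate_id, wells=wells)


def layout_from_frame(df: pd.DataFrame) -> PlateLayout:
    """Rebuild a :class:`PlateLayout` from its CSV table form."""
    required = {"plate_id", "well", "role", "gene_symbol", "duplex_index"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"layout table missing columns: {sorted(missing)}")
    plate_ids = df["plate_id"].unique()
    if len(plate_ids) != 1:
        raise LayoutError(f"layout table must describe one plate, got {list(plate_ids)}")
    wells = {}
    for _, r in df.iterrows():
        gene = "" if pd.isna(r["gene_symbol"]) else str(r["gene_symbol"])
        wells[str(r["well"])] = WellSpec(
            role=str(r["role"]), gene_symbol=gene, duplex_index=int(r["duplex_index"])
        )
    return PlateLayout(plate_id=str(plate_ids[0]), wells=wells)
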