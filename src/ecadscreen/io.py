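"""Readers and writers for on-disk screen artifacts.

Well tables, plate layouts and reports are comma-separated UTF-8 CSV with
"." decimals; sequences are FASTA (via Biopython) or two-column TSV; field
images are 16-bit two-channel TIFF. Every writer/reader pair round-trips
bit-exactly on records.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .errors import ParseError
from .layouts import PlateLayout, layout_from_frame, well_index

WELL_TABLE_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "gene_symbol",
    "duplex_index",
    "cell_count",
    "fov_used",
    "sparse_terminated",
    "ecad_raw",
]

RNA_ALPHABET = frozenset("ACGU")


# --------------------------------------------------------------- well tables
def read_well_table(path: str | Path, layout: PlateLayout | None = None) -> pd.DataFrame:
    """Read a well-level measurement table, validating against ``layout``.

    Roles/genes/duplexes are back-filled from the layout when the table
    omits them. Row order is preserved. Raises :class:`ParseError` naming
    the offending row on any invariant violation.
    """
    try:
        df = pd.read_csv(path, dtype={"well": str, "plate_id": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read well table {path}: {exc}") from exc
    required = {"plate_id", "well", "cell_count", "fov_used", "ecad_raw"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    if layout is not None:
        spec_lookup = layout.wells
        roles, genes, duplexes = [], [], []
        for i, r in df.iterrows():
            well = str(r["well"])
            try:
                well_index(well)
            except Exception as exc:
                raise ParseError(f"{path} row {i}: {exc}") from exc
            if well not in spec_lookup:
                raise ParseError(f"{path} row {i}: well {well} not in layout")
            spec = spec_lookup[well]
            roles.append(spec.role)
            genes.append(spec.gene_symbol)
            duplexes.append(spec.duplex_index)
        df["role"] = roles
        df["gene_symbol"] = genes
        df["duplex_index"] = duplexes
    else:
        for col in ("role", "gene_symbol", "duplex_index"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing column {col!r} and no layout given")

    for i, r in df.iterrows():
        if r["cell_count"] < 0:
            raise ParseError(f"{path} row {i}: negative cell_count {r['cell_count']}")
        if r["ecad_raw"] < 0:
            raise ParseError(f"{path} row {i}: negative ecad_raw {r['ecad_raw']}")
        if not (1 <= r["fov_used"]):
            raise ParseError(f"{path} row {i}: fov_used must be >= 1")
    if "sparse_terminated" not in df.columns:
        df["sparse_terminated"] = False
    df["sparse_terminated"] = df["sparse_terminated"].astype(bool)
    df["duplex_index"] = df["duplex_index"].astype(int)
    df["cell_count"] = df["cell_count"].astype(float)
    df["fov_used"] = df["fov_used"].astype(int)
    df["ecad_raw"] = df["ecad_raw"].astype(float)
    return df[WELL_TABLE_COLUMNS]


def write_well_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(WELL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"well table missing columns: {sorted(missing)}")
    df[WELL_TABLE_COLUMNS].to_csv(path, index=False)


# ------------------------------------------------------------------ layouts
def write_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, index=False)


def read_layout(path: str | Path) -> PlateLayout:
    df = pd.read_csv(path, dtype={"well": str, "plate_id": str, "gene_symbol": str})
    return layout_from_frame(df)


# ---------------------------------------------------------------- sequences
def _clean_sequence(name: str, seq: str) -> str:
    """Upper-case, map DNA T to RNA U, reject non-nucleotide characters."""
    rna = str(seq).strip().upper().replace("T", "U")
    bad = set(rna) - RNA_ALPHABET
    if bad:
        raise ParseError(
            f"sequence {name!r} contains non-nucleotide characters: {sorted(bad)}"
        )
    return rna


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read named RNA sequences from FASTA or two-column TSV.

    DNA-alphabet input is mapped T->U. Names must be unique.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        for record in SeqIO.parse(str(path), "fasta"):
            entries.append((record.id, _clean_sequence(record.id, str(record.seq))))
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected two tab-separated columns")
        for _, r in df.iterrows():
            entries.append((str(r[0]), _clean_sequence(str(r[0]), r[1])))
    names = [n for n, _ in entries]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate sequence names {sorted(dupes)}")
    return entries


def read_duplex_table(path: str | Path) -> pd.DataFrame:
    """Read a duplex table: columns gene, duplex_index, sense, antisense (5'->3')."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "duplex_index", "sense", "antisense"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["duplex_index"] = df["duplex_index"].astype(int)
    for col in ("sense", "antisense"):
        df[col] = [
            _clean_sequence(f"{g}#{d}", s)
            for g, d, s in zip(df["gene"], df["duplex_index"], df[col])
        ]
    return df


def write_duplex_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene", "duplex_index", "sense", "antisense"]].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- expression
def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene_symbol": str})
    if not {"gene_symbol", "rpkm"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns gene_symbol, rpkm")
    if (df["rpkm"] < 0).any():
        raise ParseError(f"{path}: negative RPKM values")
    return df


# ------------------------------------------------------------------- images
def write_field_image(channel1: np.ndarray, channel2: np.ndarray, path: str | Path) -> None:
    """Write a two-channel 16-bit field TIFF (axes CYX)."""
    stack = np.stack([channel1, channel2]).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack", metadata={"axes": "CYX"})


def read_field_image(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ParseError(f"{path}: expected a 2-channel image, got shape {stack.shape}")
    return stack[0], stack[1]


# ------------------------------------------------------------------ reports
REPORT_COLUMNS = [
    "gene_symbol",
    "fold_ecad",
    "fold_count",
    "z_ecad",
    "ecad_bin",
    "cv_bin",
    "fov_used",
    "pro_survival",
    "anti_proliferative",
    "rpkm",
    "seed_matched",
    "candidate_class",
    "n_active",
    "validated",
    "final_class",
    "filter_trail",
]


def _encode_trail(trail) -> str:
    """Serialize a filter trail (list of (filter, passed)) losslessly."""
    if isinstance(trail, str):
        return trail
    return json.dumps([[str(n), bool(p)] for n, p in trail])


def _decode_trail(s: str):
    if s == "" or pd.isna(s):
        return []
    return [(n, bool(p)) for n, p in json.loads(s)]


def write_screen_report(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene report with its full filter trail, in fixed column order."""
    df = results.copy()
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "filter_trail" else np.nan
    df["filter_trail"] = [_encode_trail(t) for t in df["filter_trail"]]
    df[REPORT_COLUMNS].to_csv(path, index=False)


def read_screen_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene_symbol": str, "filter_trail": str})
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: report missing columns {sorted(missing)}")
    df["filter_trail"] = [_decode_trail(t) for t in df["filter_trail"]]
    return df[REPORT_COLUMNS]
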