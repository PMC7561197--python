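"""Plate normalization: replicate averaging, fold-to-mock, robust Z.

Order of operations follows the screening workflow: duplicate plates are
averaged on raw values first; each well's raw Ecad score and cell count are
then divided by the arithmetic mean of the same plate's mock wells; finally
an inter-plate robust Z-score, (x - median) / (1.4826 * MAD), is computed
over the library sample wells of the whole screen (controls excluded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .layouts import ROLE_MOCK, ROLE_SAMPLE

#: consistency constant making MAD estimate the SD of a normal distribution
MAD_CONSISTENCY = 1.4826

_KEY = ["plate_id", "well"]
_ANNOT = ["role", "gene_symbol", "duplex_index"]


def _strip_replicate_suffix(plate_id: pd.Series) -> pd.Series:
    """'P001_A' / 'P001_B' -> 'P001'; ids without a replicate suffix pass through."""
    return plate_id.str.replace(r"_[AB]$", "", regex=True)


def average_replicates(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Average raw cell counts and Ecad scores over duplicate plates.

    Both tables must cover identical (plate, well) sets with identical
    annotations; ``fov_used`` averages too (it feeds the proliferation
    classification). Commutative in its arguments.
    """
    a = table_a.copy()
    b = table_b.copy()
    a["plate_id"] = _strip_replicate_suffix(a["plate_id"].astype(str))
    b["plate_id"] = _strip_replicate_suffix(b["plate_id"].astype(str))
    a_keys = set(map(tuple, a[_KEY].itertuples(index=False)))
    b_keys = set(map(tuple, b[_KEY].itertuples(index=False)))
    if a_keys != b_keys:
        missing = sorted(a_keys ^ b_keys)[:5]
        raise ValidationError(f"replicate tables cover different wells, e.g. {missing}")
    merged = a.merge(b, on=_KEY, suffixes=("_a", "_b"), validate="one_to_one")
    for col in _ANNOT:
        if not (merged[f"{col}_a"].fillna("") == merged[f"{col}_b"].fillna("")).all():
            raise ValidationError(f"replicate tables disagree on annotation {col!r}")
    out = merged[_KEY].copy()
    for col in _ANNOT:
        out[col] = merged[f"{col}_a"]
    for col in ("cell_count", "ecad_raw", "fov_used"):
        out[col] = (merged[f"{col}_a"] + merged[f"{col}_b"]) / 2.0
    out["sparse_terminated"] = merged["sparse_terminated_a"] | merged["sparse_terminated_b"]
    return out


def fold_vs_mock(table: pd.DataFrame) -> pd.DataFrame:
    """Intra-plate normalization: divide by the plate's mock-well means.

    Adds ``fold_ecad`` and ``fold_count`` columns; mock wells themselves are
    normalized too (their folds average exactly 1 per plate). A zero or
    absent mock mean raises rather than propagating infinities.
    """
    out = table.copy()
    out["fold_ecad"] = np.nan
    out["fold_count"] = np.nan
    for plate_id, plate in table.groupby("plate_id"):
        mocks = plate[plate["role"] == ROLE_MOCK]
        if mocks.empty:
            raise ValidationError(f"plate {plate_id!r} has no mock wells")
        mock_ecad = float(mocks["ecad_raw"].mean())
        mock_count = float(mocks["cell_count"].mean())
        if not np.isfinite(mock_ecad) or mock_ecad <= 0:
            raise DegenerateInputError(
                f"plate {plate_id!r}: mock Ecad mean is {mock_ecad}; cannot normalize"
            )
        if not np.isfinite(mock_count) or mock_count <= 0:
            raise DegenerateInputError(
                f"plate {plate_id!r}: mock cell-count mean is {mock_count}"
            )
        idx = plate.index
        out.loc[idx, "fold_ecad"] = plate["ecad_raw"] / mock_ecad
        out.loc[idx, "fold_count"] = plate["cell_count"] / mock_count
    return out


def robust_z(values) -> np.ndarray:
    """Robust Z-scores: (x - median) / (1.4826 * MAD).

    The median entry of any input maps to 0; the statistic is invariant to
    multiplying all values by a positive constant after centring. Raises on
    MAD = 0 (degenerate, typically an all-identical synthetic input).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("robust_z requires at least 3 entries")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateInputError(
            "MAD of the fold distribution is 0; the input is degenerate "
            "(all values identical?) - add spread or use more wells"
        )
    return (x - med) / (MAD_CONSISTENCY * mad)


def score_screen(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Full normalization chain: average replicates, fold-to-mock, robust Z.

    Returns a per-well table with ``fold_ecad``, ``fold_count`` and
    ``z_ecad``; the Z reference population is the library sample wells of
    the whole screen (controls excluded), matching the single global Z
    distribution of the workflow.
    """
    averaged = average_replicates(table_a, table_b)
    folded = fold_vs_mock(averaged)
    folded["z_ecad"] = np.nan
    is_sample = folded["role"] == ROLE_SAMPLE
    if is_sample.sum() >= 3:
        sample_folds = folded.loc[is_sample, "fold_ecad"].to_numpy()
        med = np.median(sample_folds)
        mad = np.median(np.abs(sample_folds - med))
        if mad == 0:
            raise DegenerateInputError("sample fold MAD is 0; cannot Z-score")
        folded["z_ecad"] = (folded["fold_ecad"] - med) / (MAD_CONSISTENCY * mad)
    return folded


def gene_scores(scored: pd.DataFrame) -> pd.DataFrame:
    """Collapse a scored well table to one row per (gene, duplex).

    For the primary screen each gene occupies one well per plate pair, so
    this is a pass-through; in deconvolution it averages replicate wells.
    """
    samples = scored[scored["role"] == ROLE_SAMPLE]
    grouped = (
        samples.groupby(["gene_symbol", "duplex_index"], as_index=False)
        .agg(
            fold_ecad=("fold_ecad", "mean"),
            fold_count=("fold_count", "mean"),
            z_ecad=("z_ecad", "mean"),
            cell_count=("cell_count", "mean"),
            fov_used=("fov_used", "mean"),
            n_wells=("well", "size"),
        )
    )
    return grouped
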