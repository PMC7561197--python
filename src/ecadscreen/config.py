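"""Screen configuration: every threshold and layout constant in one record.

The defaults are the operative constants of the published workflow: viability
bins CV1 (>=0.7-fold of mock), CV2 (0.5-0.7) and LC (<0.5, i.e. fewer than
1500 cells after the full 25 fields at a 3000-cell target); Ecad-score bins
High (>=1.6-fold of mock) and Low (<=0.2-fold); the audit robust-Z cutoffs
(5.16 up, 0.036 down); the RPKM >= 1 expression filter; and the 2-of-4
deconvolution rule at alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

SCHEMA_VERSION = 1

#: shortest admissible RNA sequence the seed extractor may be asked about
#: (a 19-mer siRNA guide strand)
MIN_SEQUENCE_LENGTH = 19


@dataclass(frozen=True)
class ScreenConfig:
    """All tunable constants of the screening workflow.

    Parameters are grouped as: candidate-selection thresholds (folds, Z,
    RPKM, duplex rule), acquisition constants (target cell count, field
    limits), image-analysis geometry (ring width, fibre length, detection
    thresholds in robust units), and seed-matching coordinates.
    """

    # --- Ecad-score candidate thresholds (fold vs plate mock) ---
    fold_high: float = 1.6
    fold_low: float = 0.2
    #: robust-Z equivalents of the fold cutoffs, reported for audit only
    z_high: float = 5.16
    z_low: float = 0.036

    # --- cell-viability bins (fold vs plate mock cell count) ---
    cv1_min: float = 0.7
    cv2_min: float = 0.5
    low_count_cells: int = 1500

    # --- field acquisition ---
    target_cells: int = 3000
    max_fields: int = 25
    min_cells_per_field: int = 14
    max_sparse_fields: int = 6

    # --- expression / validation ---
    rpkm_min: float = 1.0
    min_active_duplexes: int = 2
    alpha: float = 0.05
    #: Student (equal-variance) one-tailed t-test by default; Welch optional
    equal_var_ttest: bool = True

    # --- image analysis ---
    ring_width_px: int = 12
    fibre_min_length_px: int = 10
    nucleus_min_area_px: int = 40
    #: watershed seeds must be at least this far apart (px)
    nucleus_split_min_distance_px: int = 12
    #: intensity / ridge-response thresholds in robust units
    #: (median + k * 1.4826 * MAD of the field)
    nucleus_thresh_k: float = 8.0
    fibre_ridge_sigmas: tuple[float, ...] = (1.0, 1.5, 2.0)
    fibre_ridge_smooth_sigma: float = 1.0
    fibre_thresh_k_low: float = 8.0
    fibre_thresh_k_high: float = 14.0
    #: whether fibres overlapping the nuclear footprint itself are counted
    #: (the vendor "modified whole cell mask" is ambiguous on this point)
    count_fibres_in_nuclei: bool = True

    # --- seed matching (1-based coordinates on the guide strand) ---
    seed_start: int = 2
    seed_length: int = 7

    # --- provenance ---
    normalization_method: str = "fold-to-plate-mock + robust-z (1.4826*MAD)"
    rng_seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigError` on any inconsistent combination."""
        if not (self.fold_low < 1.0 < self.fold_high):
            raise ConfigError(
                f"require fold_low < 1 < fold_high, got {self.fold_low}, {self.fold_high}"
            )
        if not (0.0 < self.cv2_min < self.cv1_min):
            raise ConfigError(
                f"require 0 < cv2_min < cv1_min, got {self.cv2_min}, {self.cv1_min}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        counts = {
            "low_count_cells": self.low_count_cells,
            "target_cells": self.target_cells,
            "max_fields": self.max_fields,
            "min_cells_per_field": self.min_cells_per_field,
            "max_sparse_fields": self.max_sparse_fields,
            "min_active_duplexes": self.min_active_duplexes,
            "seed_length": self.seed_length,
            "seed_start": self.seed_start,
        }
        for name, value in counts.items():
            if value <= 0 or int(value) != value:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        # the LC bin is stated two ways in the workflow (absolute count and
        # fold of the 3000-cell target); both must agree
        expected_low = self.cv2_min * self.target_cells
        if not math.isclose(self.low_count_cells, expected_low, rel_tol=1e-12):
            raise ConfigError(
                "low_count_cells must equal cv2_min * target_cells "
                f"({self.cv2_min} * {self.target_cells} = {expected_low}), "
                f"got {self.low_count_cells}"
            )
        if self.seed_start + self.seed_length - 1 > MIN_SEQUENCE_LENGTH:
            raise ConfigError(
                "seed window extends past the shortest admissible sequence "
                f"({MIN_SEQUENCE_LENGTH} nt)"
            )
        if self.ring_width_px < 0:
            raise ConfigError("ring_width_px must be non-negative")
        if self.fibre_min_length_px <= 0:
            raise ConfigError("fibre_min_length_px must be positive")
        if self.rpkm_min < 0:
            raise ConfigError("rpkm_min must be non-negative")
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.schema_version!r}; "
                f"this build reads version {SCHEMA_VERSION}"
            )

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fibre_ridge_sigmas"] = list(self.fibre_ridge_sigmas)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScreenConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "fibre_ridge_sigmas" in data:
            data = dict(data)
            data["fibre_ridge_sigmas"] = tuple(data["fibre_ridge_sigmas"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def replace(self, **changes) -> "ScreenConfig":
        return dataclasses.replace(self, **changes)


DEFAULT_CONFIG = ScreenConfig()
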