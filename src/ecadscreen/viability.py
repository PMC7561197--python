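"""Cell-viability binning and proliferation classification.

Wells are binned on their cell-count fold versus the plate mock: CV1
(>= 0.7), CV2 (>= 0.5 and < 0.7) and LC (< 0.5). LC wells - equivalently
fewer than 1500 cells after the full 25 fields at the 3000-cell target -
mark pro-survival genes and are excluded from E-cadherin candidacy.
Anti-proliferative genes are the opposite tail: they reach the target cell
count at two standard deviations fewer fields than the mock mean while
leaving the Ecad score unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, ScreenConfig
from .errors import DegenerateInputError, ValidationError

CV1 = "CV1"
CV2 = "CV2"
LC = "LC"


@dataclass(frozen=True)
class ViabilityCall:
    """Per-gene viability classification."""

    gene_symbol: str
    cv_bin: str
    pro_survival: bool
    anti_proliferative: bool
    fov_used: float

    def __post_init__(self):
        if self.pro_survival and self.cv_bin != LC:
            raise ValidationError("pro_survival requires the LC bin")
        if self.pro_survival and self.anti_proliferative:
            raise ValidationError("pro_survival and anti_proliferative are exclusive")


def bin_viability(fold_count: float, config: ScreenConfig = DEFAULT_CONFIG) -> str:
    """Bin a cell-count fold into CV1 / CV2 / LC (exhaustive on [0, inf))."""
    if fold_count < 0 or not np.isfinite(fold_count):
        raise ValidationError(f"fold_count must be finite and >= 0, got {fold_count}")
    if fold_count >= config.cv1_min:
        return CV1
    if fold_count >= config.cv2_min:
        return CV2
    return LC


def classify_pro_survival(
    cell_count: float, fov_used: float, config: ScreenConfig = DEFAULT_CONFIG
) -> bool:
    """Pro-survival flag: strictly fewer than 1500 cells in the full 25 fields.

    This is the absolute-count formulation of the LC bin: a well that
    consumed every allowed field yet stayed under ``low_count_cells``.
    """
    return fov_used >= config.max_fields and cell_count < config.low_count_cells


def fov_cutoff(mock_fov_used, config: ScreenConfig = DEFAULT_CONFIG) -> tuple[int, float]:
    """Fast-proliferation FOV cutoff from the mock wells' field usage.

    Returns ``(cutoff, raw)`` where ``raw = mean - 2*sd`` and ``cutoff`` is
    its ceiling; a gene classifies as fast when ``fov_used <= cutoff``.
    With the published mock statistics (mean 20, SD 3.13) the cutoff is 14,
    i.e. the "<15 FOV" rule.
    """
    fov = np.asarray(list(mock_fov_used), dtype=float)
    if fov.size < 2:
        raise ValidationError("fov_cutoff requires at least 2 mock values")
    mean = float(fov.mean())
    sd = float(fov.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError(
            f"mock FOV standard deviation is 0 (all wells used {mean:g} fields); "
            "the cutoff is undefined - supply mocks with natural variation"
        )
    raw = mean - 2.0 * sd
    return int(math.ceil(raw)), raw


def classify_anti_proliferative(
    fov_used: float, cutoff: int, ecad_bin: str
) -> bool:
    """Anti-proliferative: target reached in <= cutoff fields AND Ecad bin NC.

    A gene that also moves the Ecad score is a regulator, not an
    anti-proliferative call (the regulator phenotype takes precedence).
    """
    return fov_used <= cutoff and ecad_bin == "NC"


def call_viability(
    gene_symbol: str,
    fold_count: float,
    cell_count: float,
    fov_used: float,
    ecad_bin: str,
    cutoff: int,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> ViabilityCall:
    """Combine the bins and flags into one per-gene viability call.

    The LC bin is evaluated on the absolute-count rule and cross-checked
    against the fold formulation; a disagreement (possible on wells that
    stopped early) resolves in favour of the fold bin, which is the
    operative exclusion criterion of the cascade.
    """
    cv = bin_viability(fold_count, config)
    pro = classify_pro_survival(cell_count, fov_used, config)
    if pro and cv != LC:
        # absolute-count LC without fold LC: inconsistent input; trust folds
        pro = False
    # an LC-bin well that stopped early (sparse run) is still a low-count
    # exclusion, never a fast-proliferation call
    anti = (
        (not pro)
        and cv != LC
        and classify_anti_proliferative(fov_used, cutoff, ecad_bin)
    )
    return ViabilityCall(
        gene_symbol=gene_symbol,
        cv_bin=cv,
        pro_survival=pro,
        anti_proliferative=anti,
        fov_used=fov_used,
    )
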