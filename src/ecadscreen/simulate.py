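"""Synthetic screen generator with exact ground truth.

Emulates the raw material of a genome-wide high-content siRNA screen in
384-well plates: two-channel field images (nuclei + junctional E-cadherin
"fibres"), duplicate well-level plate tables with planted effect classes,
4-duplex siRNA sets with optional miR-200-family seed carriers, and an RPKM
expression table with a low-expression fraction.

Noise model: multiplicative log-normal on per-well Ecad scores and cell
densities; Poisson on per-well fibre totals and per-field cell counts.
Every generator is a pure function of (spec, seed); per-plate/-well/-field
substreams are derived by hashing so partial regeneration is reproducible.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import DEFAULT_CONFIG, ScreenConfig
from .errors import ValidationError
from .image_quant import acquire_fields
from .layouts import (
    PlateLayout,
    ROLE_EMPTY,
    ROLE_MOCK,
    ROLE_SAMPLE,
    ROLE_SICDH1,
    ROLE_SIPLK1,
    ROLE_SIZEB1,
    deconvolution_layout,
    primary_layout,
)

EFFECT_CLASSES = ("null", "ecad_up", "ecad_down", "toxic", "anti_proliferative")

RNA_BASES = np.array(list("ACGU"))
_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def derive_seed(root_seed: int, *tokens) -> int:
    """Deterministic substream seed from a root seed and context tokens."""
    h = hashlib.sha256(repr((int(root_seed),) + tuple(map(str, tokens))).encode())
    return int.from_bytes(h.digest()[:8], "little") % (2**63)


# ============================================================= effect specs
@dataclass(frozen=True)
class EffectSpec:
    """Planted per-gene ground truth for the screen generator."""

    gene_symbol: str
    effect_class: str = "null"
    ecad_fold_effect: float = 1.0
    count_fold_effect: float = 1.0
    seed_carrier_duplexes: frozenset = frozenset()
    n_active_duplexes: int = 0

    def __post_init__(self):
        if self.effect_class not in EFFECT_CLASSES:
            raise ValidationError(f"unknown effect class {self.effect_class!r}")
        if not (0 <= self.n_active_duplexes <= 4):
            raise ValidationError("n_active_duplexes must be 0-4")
        if not self.seed_carrier_duplexes <= {1, 2, 3, 4}:
            raise ValidationError("seed_carrier_duplexes must be a subset of {1..4}")
        if self.ecad_fold_effect < 0 or self.count_fold_effect < 0:
            raise ValidationError("fold effects must be non-negative")

    def validate_against(self, config: ScreenConfig = DEFAULT_CONFIG) -> None:
        """Check the class/effect consistency contracts."""
        c = self.effect_class
        if c == "ecad_up" and self.ecad_fold_effect < config.fold_high:
            raise ValidationError(
                f"{self.gene_symbol}: ecad_up requires fold >= {config.fold_high}"
            )
        if c == "ecad_down" and self.ecad_fold_effect > config.fold_low:
            raise ValidationError(
                f"{self.gene_symbol}: ecad_down requires fold <= {config.fold_low}"
            )
        if c == "toxic" and self.count_fold_effect >= config.cv2_min:
            raise ValidationError(
                f"{self.gene_symbol}: toxic requires count fold < {config.cv2_min}"
            )
        if c == "anti_proliferative":
            if self.count_fold_effect <= 1.0:
                raise ValidationError(
                    f"{self.gene_symbol}: anti_proliferative requires count fold > 1"
                )
            if not (config.fold_low < self.ecad_fold_effect < config.fold_high):
                raise ValidationError(
                    f"{self.gene_symbol}: anti_proliferative Ecad fold must stay in "
                    f"({config.fold_low}, {config.fold_high})"
                )

    @property
    def active_duplexes(self) -> frozenset:
        """Which of duplexes 1-4 move the Ecad score in deconvolution.

        Seed carriers are always active (the off-target drives the score);
        on-target active duplexes fill the remainder in index order.
        """
        active = set(self.seed_carrier_duplexes)
        for d in (1, 2, 3, 4):
            if len(active) >= self.n_active_duplexes:
                break
            if d not in active:
                active.add(d)
        return frozenset(active)


def null_gene(name: str) -> EffectSpec:
    return EffectSpec(name, "null")


def ecad_up_gene(name: str, fold: float = 2.0, n_active: int = 4) -> EffectSpec:
    return EffectSpec(name, "ecad_up", ecad_fold_effect=fold, n_active_duplexes=n_active)


def ecad_down_gene(name: str, fold: float = 0.1, n_active: int = 4) -> EffectSpec:
    return EffectSpec(name, "ecad_down", ecad_fold_effect=fold, n_active_duplexes=n_active)


def toxic_gene(name: str, count_fold: float = 0.3) -> EffectSpec:
    return EffectSpec(name, "toxic", count_fold_effect=count_fold)


def anti_proliferative_gene(name: str, count_fold: float = 1.5) -> EffectSpec:
    return EffectSpec(name, "anti_proliferative", count_fold_effect=count_fold)


def seed_artifact_gene(name: str, fold: float = 2.0, carrier: int = 1) -> EffectSpec:
    """A gene whose pool Ecad increase is driven by one seed-carrying duplex."""
    return EffectSpec(
        name,
        "ecad_up",
        ecad_fold_effect=fold,
        seed_carrier_duplexes=frozenset({carrier}),
        n_active_duplexes=1,
    )


# ============================================================ field images
@dataclass
class FieldImage:
    """One acquired two-channel field (channel1 nuclei, channel2 E-cadherin)."""

    channel1: np.ndarray
    channel2: np.ndarray


@dataclass
class FieldTruth:
    """Exact planted geometry for one field."""

    nucleus_centres: np.ndarray  # (n, 2) float, (row, col)
    n_fibres: int
    fibre_rate: float  # the per-cell rate lambda used


def _sample_centres(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    margin: float,
) -> np.ndarray:
    """Rejection-sample n points with pairwise distance >= min_separation."""
    centres: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * max(n, 1)
    while len(centres) < n:
        if attempts > max_attempts:
            raise ValidationError(
                f"cannot place {n} nuclei at separation {min_separation} in field {shape}"
            )
        attempts += 1
        p = np.array(
            [
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            ]
        )
        if all(np.hypot(*(p - q)) >= min_separation for q in centres):
            centres.append(p)
    return np.array(centres).reshape(n, 2)


def _paint_gaussian_blob(img: np.ndarray, centre, sigma: float, amplitude: float) -> None:
    r0, c0 = centre
    rad = int(math.ceil(3 * sigma))
    r_lo, r_hi = max(0, int(r0) - rad), min(img.shape[0], int(r0) + rad + 1)
    c_lo, c_hi = max(0, int(c0) - rad), min(img.shape[1], int(c0) + rad + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


def make_field_image(
    n_cells: int,
    lam: float,
    noise: float = 20.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (512, 512),
    min_separation: float = 40.0,
    nucleus_sigma: float = 4.0,
    nucleus_amplitude: float = 3000.0,
    fibre_amplitude: float = 1800.0,
    fibre_length: float = 30.0,
    background: float = 200.0,
) -> tuple[FieldImage, FieldTruth]:
    """Draw one synthetic field with ``n_cells`` nuclei and planted fibres.

    Channel 1 holds non-touching Gaussian nucleus blobs; channel 2 holds
    approximately ``Poisson(n_cells * lam)`` anti-aliased curvilinear fibre
    arcs hugging cell-boundary radii around the nuclei, over an additive
    Gaussian background. ``lam = 0`` plants exactly zero fibre structures
    (the siCDH1 phenotype). Identical seeds give byte-identical images.
    """
    if n_cells < 0 or lam < 0:
        raise ValidationError("n_cells and lam must be non-negative")
    rng = np.random.default_rng(seed)
    ch1 = np.full(shape, background, dtype=float)
    ch2 = np.full(shape, background, dtype=float)

    centres = _sample_centres(rng, n_cells, shape, min_separation, margin=nucleus_sigma * 4)
    for centre in centres:
        amp = nucleus_amplitude * rng.uniform(0.8, 1.2)
        sig = nucleus_sigma * rng.uniform(0.9, 1.1)
        _paint_gaussian_blob(ch1, centre, sig, amp)

    n_fibres_target = int(rng.poisson(n_cells * lam)) if (n_cells > 0 and lam > 0) else 0
    fg = np.zeros(shape, dtype=float)
    occupied = np.zeros(shape, dtype=bool)
    n_drawn = 0
    if n_fibres_target > 0:
        # offsets of a radius-12 exclusion disk around each painted arc
        # point; keeps planted fibres far enough apart that ridge detection
        # sees them as separate structures
        dr, dc = np.mgrid[-12:13, -12:13]
        disk = np.stack([dr[dr**2 + dc**2 <= 144], dc[dr**2 + dc**2 <= 144]], axis=1)
        for _ in range(n_fibres_target):
            for _attempt in range(40):
                centre = centres[rng.integers(len(centres))]
                radius = rng.uniform(min_separation * 0.3, min_separation * 0.45)
                theta0 = rng.uniform(0, 2 * math.pi)
                dtheta = fibre_length / radius
                ts = np.arange(0, dtheta, 0.4 / radius)
                pts = np.stack(
                    [
                        centre[0] + radius * np.cos(theta0 + ts),
                        centre[1] + radius * np.sin(theta0 + ts),
                    ],
                    axis=1,
                )
                ipts = np.round(pts).astype(int)
                if (
                    (ipts < 1).any()
                    or (ipts[:, 0] >= shape[0] - 1).any()
                    or (ipts[:, 1] >= shape[1] - 1).any()
                ):
                    continue
                if occupied[ipts[:, 0], ipts[:, 1]].any():
                    continue
                # paint a ~2 px ribbon: the arc plus half-pixel parallel offsets
                normal = np.stack(
                    [np.cos(theta0 + ts), np.sin(theta0 + ts)], axis=1
                )
                for off in (-0.7, 0.0, 0.7):
                    opts = np.round(pts + off * normal).astype(int)
                    fg[opts[:, 0], opts[:, 1]] = fibre_amplitude
                excl = (ipts[:, None, :] + disk[None, :, :]).reshape(-1, 2)
                excl = np.clip(excl, 0, [shape[0] - 1, shape[1] - 1])
                occupied[excl[:, 0], excl[:, 1]] = True
                n_drawn += 1
                break
    ch2 += gaussian_filter(fg, 0.7)

    ch1 += rng.normal(0.0, noise, size=shape)
    ch2 += rng.normal(0.0, noise, size=shape)
    image = FieldImage(
        channel1=np.clip(ch1, 0, 65535).astype(np.uint16),
        channel2=np.clip(ch2, 0, 65535).astype(np.uint16),
    )
    truth = FieldTruth(nucleus_centres=centres, n_fibres=n_drawn, fibre_rate=lam)
    return image, truth


# ============================================================ whole screens
@dataclass
class ScreenTruth:
    """Ground truth for a generated screen."""

    effects: dict[str, EffectSpec]
    mock_ecad_raw: float
    mock_field_density: float
    plate_biases: dict[str, float] = field(default_factory=dict)


#: control-well effect folds (ecad_fold, count_fold) used by the generator
CONTROL_EFFECTS = {
    ROLE_MOCK: (1.0, 1.0),
    ROLE_SIZEB1: (2.2, 1.0),  # strong Ecad increase, the positive-bin control
    ROLE_SICDH1: (0.0, 1.0),  # raw score exactly 0, no toxicity
    ROLE_SIPLK1: (1.0, 0.3),  # toxicity control
    ROLE_EMPTY: (0.0, 0.015),  # stray cells only
}


def _simulate_well(
    rng: np.random.Generator,
    ecad_fold: float,
    count_fold: float,
    config: ScreenConfig,
    noise_sd: float,
    mock_ecad_raw: float,
    mock_field_density: float,
    plate_bias: float = 1.0,
) -> dict:
    """One well: noisy density -> field-by-field acquisition -> raw Ecad score."""
    density = mock_field_density * count_fold * plate_bias * rng.lognormal(0.0, noise_sd)
    field_counts = rng.poisson(max(density, 1e-9), size=config.max_fields)
    acq = acquire_fields(field_counts, config)
    if ecad_fold > 0:
        ecad_raw = mock_ecad_raw * ecad_fold * plate_bias * rng.lognormal(0.0, noise_sd)
    else:
        ecad_raw = 0.0
    return {
        "cell_count": float(acq.total_cells),
        "fov_used": int(acq.fields_used),
        "sparse_terminated": acq.terminated_by == "sparse_run",
        "ecad_raw": float(ecad_raw),
    }


def _screen_tables(
    layouts: Sequence[PlateLayout],
    effects: dict[str, EffectSpec],
    config: ScreenConfig,
    noise_sd: float,
    seed: int,
    mock_ecad_raw: float,
    mock_field_density: float,
    plate_bias_sd: float,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    tables = {"A": [], "B": []}
    biases: dict[str, float] = {}
    for layout in layouts:
        bias_rng = np.random.default_rng(derive_seed(seed, "plate_bias", layout.plate_id))
        bias = bias_rng.lognormal(0.0, plate_bias_sd) if plate_bias_sd > 0 else 1.0
        biases[layout.plate_id] = bias
        for rep in ("A", "B"):
            rows = []
            for well in sorted(layout.wells):
                spec = layout.wells[well]
                if spec.role == ROLE_SAMPLE:
                    eff = effects[spec.gene_symbol]
                    if spec.duplex_index == 0:
                        ecad_fold = eff.ecad_fold_effect
                        count_fold = eff.count_fold_effect
                    else:  # deconvolution well: one duplex
                        if spec.duplex_index in eff.active_duplexes:
                            ecad_fold = eff.ecad_fold_effect
                            count_fold = eff.count_fold_effect
                        else:
                            ecad_fold, count_fold = 1.0, 1.0
                else:
                    ecad_fold, count_fold = CONTROL_EFFECTS[spec.role]
                rng = np.random.default_rng(
                    derive_seed(seed, layout.plate_id, rep, well)
                )
                meas = _simulate_well(
                    rng,
                    ecad_fold,
                    count_fold,
                    config,
                    noise_sd,
                    mock_ecad_raw,
                    mock_field_density,
                    bias,
                )
                rows.append(
                    {
                        "plate_id": f"{layout.plate_id}_{rep}",
                        "well": well,
                        "role": spec.role,
                        "gene_symbol": spec.gene_symbol,
                        "duplex_index": spec.duplex_index,
                        **meas,
                    }
                )
            tables[rep].append(pd.DataFrame(rows))
    return (
        pd.concat(tables["A"], ignore_index=True),
        pd.concat(tables["B"], ignore_index=True),
        biases,
    )


def make_screen(
    genes: Sequence[EffectSpec],
    config: ScreenConfig = DEFAULT_CONFIG,
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    mock_ecad_raw: float = 1.0,
    mock_field_density: float = 150.0,
    plate_bias_sd: float = 0.0,
    plate_prefix: str = "P",
) -> tuple[pd.DataFrame, pd.DataFrame, list[PlateLayout], ScreenTruth]:
    """Generate the primary SMARTpool screen: duplicate plate tables + truth.

    Mock wells draw from the null distribution; siZEB1/siCDH1/siPLK1 carry
    their control phenotypes (Ecad up / raw score 0 / toxic); sample wells
    apply their :class:`EffectSpec` multiplicatively on the mock mean with
    log-normal noise of ``noise_sd``. The default mock conditions reproduce
    the published acquisition behaviour: ~150 cells/field so mock wells
    reach the 3000-cell target in ~20 of the maximum 25 fields.
    """
    effects = {g.gene_symbol: g for g in genes}
    if len(effects) != len(genes):
        raise ValidationError("duplicate gene symbols in effect list")
    for g in genes:
        g.validate_against(config)
    per_plate = 320
    layouts = []
    gene_names = [g.gene_symbol for g in genes]
    for i in range(0, max(len(gene_names), 1), per_plate):
        chunk = gene_names[i : i + per_plate]
        layouts.append(primary_layout(f"{plate_prefix}{i // per_plate + 1:03d}", chunk))
    table_a, table_b, biases = _screen_tables(
        layouts, effects, config, noise_sd, seed, mock_ecad_raw,
        mock_field_density, plate_bias_sd,
    )
    truth = ScreenTruth(effects, mock_ecad_raw, mock_field_density, biases)
    return table_a, table_b, layouts, truth


def make_deconvolution_screen(
    genes: Sequence[EffectSpec],
    config: ScreenConfig = DEFAULT_CONFIG,
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    reps_per_duplex: int = 3,
    mock_ecad_raw: float = 1.0,
    mock_field_density: float = 150.0,
    plate_bias_sd: float = 0.0,
    plate_prefix: str = "D",
) -> tuple[pd.DataFrame, pd.DataFrame, list[PlateLayout], ScreenTruth]:
    """Generate the deconvolution screen: 4 duplexes/gene, replicated wells.

    Each gene's active duplexes (per its :class:`EffectSpec`) express the
    gene effect; inactive duplexes behave as null. Duplicate plates are
    produced, as in the primary screen.
    """
    effects = {g.gene_symbol: g for g in genes}
    entries = [
        (g.gene_symbol, d)
        for g in genes
        for d in (1, 2, 3, 4)
        for _ in range(reps_per_duplex)
    ]
    per_plate = 320
    layouts = []
    for i in range(0, max(len(entries), 1), per_plate):
        chunk = entries[i : i + per_plate]
        layouts.append(
            deconvolution_layout(f"{plate_prefix}{i // per_plate + 1:03d}", chunk)
        )
    table_a, table_b, biases = _screen_tables(
        layouts, effects, config, noise_sd, seed, mock_ecad_raw,
        mock_field_density, plate_bias_sd,
    )
    truth = ScreenTruth(effects, mock_ecad_raw, mock_field_density, biases)
    return table_a, table_b, layouts, truth


# ============================================================= duplex sets
def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA_BASES[rng.integers(0, 4, size=length)])


def reverse_complement_rna(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def make_duplex_set(
    gene: str,
    family_seed: str | Iterable[str] | None = None,
    n_matching: int = 0,
    seed: int = 0,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Generate a 4-duplex siRNA set (19-mer sense/antisense strands).

    Exactly ``n_matching`` antisense (guide) strands carry ``family_seed``
    at the configured seed window (guide positions 2-8 by default); all
    other guides are exhaustively verified seed-free against every given
    family seed. Duplexes 1..n_matching are the carriers.
    """
    seeds = []
    if family_seed is not None:
        seeds = [family_seed] if isinstance(family_seed, str) else list(family_seed)
        for s in seeds:
            if len(s) != config.seed_length:
                raise ValidationError(
                    f"family seed {s!r} has length {len(s)}, expected {config.seed_length}"
                )
    if not (0 <= n_matching <= 4):
        raise ValidationError("n_matching must be 0-4")
    if n_matching > 0 and not seeds:
        raise ValidationError("n_matching > 0 requires a family_seed")
    rng = np.random.default_rng(derive_seed(seed, "duplex", gene))
    lo = config.seed_start - 1
    hi = lo + config.seed_length
    rows = []
    for d in (1, 2, 3, 4):
        while True:
            guide = _random_rna(rng, 19)
            if d <= n_matching:
                guide = guide[:lo] + seeds[(d - 1) % len(seeds)] + guide[hi:]
                break
            if guide[lo:hi] not in seeds:
                break
        rows.append(
            {
                "gene": gene,
                "duplex_index": d,
                "sense": reverse_complement_rna(guide),
                "antisense": guide,
            }
        )
    return pd.DataFrame(rows)


# ========================================================= expression table
def make_expression_table(
    genes: Sequence[str],
    frac_low: float = 0.0,
    seed: int = 0,
    always_expressed: Iterable[str] = (),
) -> pd.DataFrame:
    """RPKM table: floor(frac_low * N) genes drawn below 1, the rest >= 1.

    ``always_expressed`` genes are never assigned to the low fraction (the
    low-expression slots are filled from the remaining genes).
    """
    if not (0.0 <= frac_low <= 1.0):
        raise ValidationError("frac_low must lie in [0, 1]")
    genes = list(genes)
    n_low = math.floor(frac_low * len(genes))
    protected = set(always_expressed)
    eligible = [g for g in genes if g not in protected]
    if n_low > len(eligible):
        raise ValidationError(
            f"cannot place {n_low} low-expression genes with "
            f"{len(protected)} protected of {len(genes)}"
        )
    rng = np.random.default_rng(derive_seed(seed, "expression"))
    low_set = set(rng.choice(eligible, size=n_low, replace=False)) if n_low else set()
    rpkm = []
    for g in genes:
        if g in low_set:
            rpkm.append(10.0 ** rng.uniform(-2.0, -0.01))  # in [0.01, 1)
        else:
            rpkm.append(10.0 ** rng.uniform(0.0, 2.5))  # in [1, ~300]
    return pd.DataFrame({"gene_symbol": genes, "rpkm": rpkm})
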