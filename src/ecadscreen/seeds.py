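"""miRNA seed-sequence off-target analysis for siRNA duplexes.

A small RNA's seed is nucleotides 2-8 of its guide strand (a heptamer by
default; the window is configurable to probe hexamer sensitivity). An siRNA
duplex whose guide-strand seed is identical to a seed of the miR-200 family
(miR-200a/b/c, miR-141, miR-429 - repressors of ZEB1 and hence drivers of
E-cadherin) can phenocopy the family by miRNA-like off-target repression,
so such genes are excluded from Ecad-High candidacy at the pool stage. A
gene is rescued at deconvolution when at least two duplexes are active of
which at least one is seed-free: the effect then cannot be explained by
the off-target alone.

Matching is exact string identity over {A,C,G,U}; no G:U wobble.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .config import DEFAULT_CONFIG, ScreenConfig
from .errors import ValidationError


@dataclass(frozen=True)
class SeedFamily:
    """A miRNA family and the deduplicated set of seeds of its members."""

    family_name: str
    members: tuple[tuple[str, str], ...]  # (miRNA name, mature RNA sequence)
    seeds: frozenset[str]

    @classmethod
    def from_members(
        cls,
        family_name: str,
        members: Iterable[tuple[str, str]],
        config: ScreenConfig = DEFAULT_CONFIG,
    ) -> "SeedFamily":
        members = tuple(members)
        seeds = frozenset(mature_to_seed(seq, config) for _, seq in members)
        return cls(family_name=family_name, members=members, seeds=seeds)


@dataclass(frozen=True)
class SeedFlag:
    """Seed-match result for one gene's 4-duplex pool."""

    gene_symbol: str
    matching_duplexes: frozenset[int]
    matched_family: str | None
    exclusion: bool

    def __post_init__(self):
        if self.exclusion and not self.matching_duplexes:
            raise ValidationError("exclusion requires at least one matching duplex")


def mature_to_seed(mature: str, config: ScreenConfig = DEFAULT_CONFIG) -> str:
    """Seed of a mature miRNA sequence: 1-based positions 2-8 by default."""
    lo = config.seed_start - 1
    hi = lo + config.seed_length
    if len(mature) < hi:
        raise ValidationError(
            f"sequence of length {len(mature)} too short for seed window "
            f"positions {config.seed_start}-{hi}"
        )
    return mature[lo:hi]


def guide_seed(duplex: Mapping, config: ScreenConfig = DEFAULT_CONFIG) -> str:
    """Seed of a duplex's antisense (guide) strand, same positional rule."""
    guide = duplex.get("antisense") if hasattr(duplex, "get") else duplex["antisense"]
    if guide is None or (isinstance(guide, float) and pd.isna(guide)) or guide == "":
        raise ValidationError("duplex record has no antisense (guide) strand")
    return mature_to_seed(str(guide), config)


def scan_pool(
    gene: str,
    duplexes: pd.DataFrame,
    families: Iterable[SeedFamily],
    config: ScreenConfig = DEFAULT_CONFIG,
) -> SeedFlag:
    """Flag which of a gene's 4 duplexes carry a family seed.

    ``duplexes`` must hold exactly 4 rows with distinct duplex_index 1-4
    and an ``antisense`` column. A duplex matches when its guide seed is
    identical to any seed in any family's seed set.
    """
    if len(duplexes) != 4:
        raise ValidationError(f"{gene}: expected exactly 4 duplexes, got {len(duplexes)}")
    indices = list(duplexes["duplex_index"])
    if sorted(indices) != [1, 2, 3, 4]:
        raise ValidationError(f"{gene}: duplex indices must be 1-4 without duplicates")
    matching: set[int] = set()
    matched_family = None
    for _, row in duplexes.iterrows():
        seed = guide_seed(row, config)
        for fam in families:
            if seed in fam.seeds:
                matching.add(int(row["duplex_index"]))
                matched_family = fam.family_name
                break
    return SeedFlag(
        gene_symbol=gene,
        matching_duplexes=frozenset(matching),
        matched_family=matched_family,
        exclusion=bool(matching),
    )


def seed_exclusion(
    flag: SeedFlag,
    duplex_active: Mapping[int, bool] | None = None,
    min_active_duplexes: int = 2,
) -> bool:
    """Decide whether a seed-flagged gene is excluded.

    Pool (SMARTpool) stage, ``duplex_active=None``: exclude whenever any
    duplex carries a family seed. Deconvolution stage: retain the gene when
    at least ``min_active_duplexes`` duplexes are active of which at least
    one is seed-free (the UBE2E3 pattern); exclude otherwise.
    """
    if not flag.matching_duplexes:
        return False
    if duplex_active is None:
        return True
    active = {d for d, a in duplex_active.items() if a}
    seed_free_active = active - set(flag.matching_duplexes)
    if len(active) >= min_active_duplexes and seed_free_active:
        return False
    return True


def scan_duplex_table(
    duplex_table: pd.DataFrame,
    families: Iterable[SeedFamily],
    config: ScreenConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Scan every gene's pool in a duplex table; one row per gene."""
    families = list(families)
    rows = []
    for gene, group in duplex_table.groupby("gene", sort=True):
        flag = scan_pool(gene, group, families, config)
        rows.append(
            {
                "gene_symbol": gene,
                "matching_duplexes": ",".join(map(str, sorted(flag.matching_duplexes))),
                "matched_family": flag.matched_family or "",
                "seed_matched": flag.exclusion,
            }
        )
    return pd.DataFrame(rows, columns=["gene_symbol", "matching_duplexes", "matched_family", "seed_matched"])


def mir200_family(config: ScreenConfig = DEFAULT_CONFIG) -> SeedFamily:
    """The bundled miR-200 family (mature sequences, miRBase v19).

    Yields the family's two seed groups, {AAUACUG} (miR-200b/c, miR-429)
    and {AACACUG} (miR-200a, miR-141). The FASTA ships with the package and
    is user-replaceable via :func:`ecadscreen.io.read_sequences`.
    """
    from .io import read_sequences  # local import to avoid a cycle

    with resources.as_file(
        resources.files("ecadscreen") / "data" / "mir200_mirbase_v19.fasta"
    ) as path:
        members = read_sequences(path)
    return SeedFamily.from_members("miR-200", members, config)
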