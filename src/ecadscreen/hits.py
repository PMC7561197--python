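"""Candidate-selection cascade and deconvolution hit validation.

The cascade runs in the workflow's order - low-count exclusion, Ecad-score
binning (keep High and Low), expression filter (RPKM >= 1), miR-200 seed
exclusion (High candidates only) - and every gene carries an ordered filter
trail proving which step it reached. Surviving candidates are re-screened
with their four individual siRNA duplexes: a duplex is *active* when a
one-tailed unpaired t-test against the mock wells is significant in the
candidate's direction AND its mean fold clears the class threshold; a gene
validates with at least 2 of 4 active duplexes. Seed-flagged genes are
rescued at deconvolution when >= 2 duplexes are active of which >= 1 is
seed-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, ScreenConfig
from .errors import ValidationError
from .seeds import SeedFlag, seed_exclusion
from .viability import LC

ECAD_HIGH = "High"
ECAD_NC = "NC"
ECAD_LOW = "Low"

CLASS_HIGH = "ecad_high"
CLASS_LOW = "ecad_low"

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"

# cascade step names, in execution order
STEP_LC = "viability_lc"
STEP_ECAD = "ecad_bin"
STEP_RPKM = "expression_rpkm"
STEP_SEED = "seed_mir200"
STEP_DECONV = "deconvolution_2of4"


@dataclass(frozen=True)
class DuplexCall:
    """One deconvolution duplex: effect size, test result, activity."""

    gene_symbol: str
    duplex_index: int
    fold_ecad: float
    p_value: float
    direction: str
    active: bool

    def __post_init__(self):
        if self.duplex_index not in (1, 2, 3, 4):
            raise ValidationError("duplex_index must be 1-4")
        if self.direction not in (DIRECTION_UP, DIRECTION_DOWN):
            raise ValidationError(f"unknown direction {self.direction!r}")


def bin_ecad(fold_ecad: float, config: ScreenConfig = DEFAULT_CONFIG) -> str:
    """Ecad-score bin: High iff fold >= 1.6, Low iff fold <= 0.2, else NC.

    Both printed cutoffs are inclusive, so a fold exactly at a cutoff is
    itself in the bin.
    """
    if fold_ecad < 0 or not np.isfinite(fold_ecad):
        raise ValidationError(f"fold_ecad must be finite and >= 0, got {fold_ecad}")
    if fold_ecad >= config.fold_high:
        return ECAD_HIGH
    if fold_ecad <= config.fold_low:
        return ECAD_LOW
    return ECAD_NC


def primary_candidates(
    gene_scores: pd.DataFrame,
    viability_calls: pd.DataFrame,
    expression: pd.DataFrame,
    seed_flags: pd.DataFrame | None = None,
    config: ScreenConfig = DEFAULT_CONFIG,
    on_missing_expression: str = "error",
) -> pd.DataFrame:
    """Run the ordered primary-screen filter cascade over all genes.

    Inputs are keyed by ``gene_symbol``: per-gene scores (``fold_ecad``,
    ``fold_count``), viability calls (``cv_bin``), an RPKM table and
    optional pool-stage seed flags (``seed_matched``). Returns one row per
    gene with its Ecad bin, candidate class (for High/Low survivors and for
    seed-flagged High genes, which stay listed for possible deconvolution
    rescue), pass/fail status and the ordered ``filter_trail``. A gene
    failing a step is never evaluated by a later one.
    """
    if on_missing_expression not in ("error", "drop"):
        raise ValidationError("on_missing_expression must be 'error' or 'drop'")
    rpkm = dict(zip(expression["gene_symbol"], expression["rpkm"]))
    cv = dict(zip(viability_calls["gene_symbol"], viability_calls["cv_bin"]))
    seed_matched: dict[str, bool] = {}
    if seed_flags is not None and len(seed_flags):
        seed_matched = dict(
            zip(seed_flags["gene_symbol"], seed_flags["seed_matched"].astype(bool))
        )

    rows = []
    for _, g in gene_scores.iterrows():
        gene = g["gene_symbol"]
        trail: list[tuple[str, bool]] = []
        ecad_bin_val = ""
        candidate_class = ""
        passed = True
        seed_flag = False

        # (1) low-count exclusion
        ok = cv.get(gene, LC) != LC
        trail.append((STEP_LC, ok))
        if not ok:
            passed = False
        else:
            # (2) Ecad binning: keep High and Low
            ecad_bin_val = bin_ecad(g["fold_ecad"], config)
            ok = ecad_bin_val != ECAD_NC
            trail.append((STEP_ECAD, ok))
            if not ok:
                passed = False
            else:
                candidate_class = CLASS_HIGH if ecad_bin_val == ECAD_HIGH else CLASS_LOW
                # (3) expression filter
                if gene not in rpkm:
                    if on_missing_expression == "error":
                        raise ValidationError(
                            f"gene {gene!r} missing from the expression table"
                        )
                    ok = False
                else:
                    ok = rpkm[gene] >= config.rpkm_min
                trail.append((STEP_RPKM, ok))
                if not ok:
                    passed = False
                else:
                    # (4) seed exclusion, High candidates only
                    if candidate_class == CLASS_HIGH:
                        seed_flag = seed_matched.get(gene, False)
                        trail.append((STEP_SEED, not seed_flag))
                        if seed_flag:
                            passed = False
        rows.append(
            {
                "gene_symbol": gene,
                "fold_ecad": g["fold_ecad"],
                "fold_count": g["fold_count"],
                "z_ecad": g.get("z_ecad", np.nan),
                "ecad_bin": ecad_bin_val,
                "candidate_class": candidate_class,
                "seed_flagged_pool": seed_flag,
                "candidate": passed,
                "filter_trail": trail,
            }
        )
    return pd.DataFrame(rows)


def duplex_activity(
    duplex_folds,
    mock_folds,
    direction: str,
    config: ScreenConfig = DEFAULT_CONFIG,
    gene_symbol: str = "",
    duplex_index: int = 1,
) -> DuplexCall:
    """Test one duplex's replicate folds against the mock folds.

    One-tailed unpaired t-test (Student by default, Welch via config) in
    the candidate's direction; the duplex is active iff p < alpha AND its
    mean fold clears the class threshold (>= fold_high for 'up',
    <= fold_low for 'down'). Both sub-criteria are reported.
    """
    x = np.asarray(list(duplex_folds), dtype=float)
    m = np.asarray(list(mock_folds), dtype=float)
    if x.size < 2 or m.size < 2:
        raise ValidationError(
            "duplex_activity needs >= 2 replicate wells on both sides "
            f"(got {x.size} duplex, {m.size} mock)"
        )
    if direction not in (DIRECTION_UP, DIRECTION_DOWN):
        raise ValidationError(f"unknown direction {direction!r}")
    alternative = "greater" if direction == DIRECTION_UP else "less"
    result = stats.ttest_ind(
        x, m, equal_var=config.equal_var_ttest, alternative=alternative
    )
    mean_fold = float(x.mean())
    if direction == DIRECTION_UP:
        clears = mean_fold >= config.fold_high
    else:
        clears = mean_fold <= config.fold_low
    p = float(result.pvalue)
    return DuplexCall(
        gene_symbol=gene_symbol,
        duplex_index=duplex_index,
        fold_ecad=mean_fold,
        p_value=p,
        direction=direction,
        active=bool(p < config.alpha and clears),
    )


def validate_gene(
    calls: list[DuplexCall], config: ScreenConfig = DEFAULT_CONFIG
) -> tuple[int, bool]:
    """2-of-4 rule: (n_active, validated) from exactly 4 duplex calls."""
    if len(calls) != 4:
        raise ValidationError(f"validate_gene expects 4 duplex calls, got {len(calls)}")
    if sorted(c.duplex_index for c in calls) != [1, 2, 3, 4]:
        raise ValidationError("duplex calls must cover indices 1-4 exactly once")
    n_active = sum(c.active for c in calls)
    return n_active, n_active >= config.min_active_duplexes


def deconvolve_candidates(
    candidates: pd.DataFrame,
    deconv_scored: pd.DataFrame,
    seed_flags: pd.DataFrame | None = None,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate candidates on a scored deconvolution well table.

    ``candidates`` is the cascade output restricted to genes worth
    deconvolving (survivors plus seed-flagged High genes awaiting rescue);
    ``deconv_scored`` is the deconvolution screen after normalization
    (per-well ``fold_ecad`` with ``role``/``gene_symbol``/``duplex_index``).
    Returns (verdicts, duplex_calls). Verdicts extend each gene's filter
    trail with the 2-of-4 step (and the seed-rescue decision where it
    applies).
    """
    mock_folds = deconv_scored.loc[
        deconv_scored["role"] == "mock", "fold_ecad"
    ].to_numpy()
    seed_match_sets: dict[str, frozenset[int]] = {}
    if seed_flags is not None and len(seed_flags):
        for _, r in seed_flags.iterrows():
            s = str(r.get("matching_duplexes", "") or "")
            seed_match_sets[r["gene_symbol"]] = frozenset(
                int(t) for t in s.split(",") if t.strip()
            )

    verdict_rows = []
    call_rows = []
    for _, cand in candidates.iterrows():
        gene = cand["gene_symbol"]
        direction = DIRECTION_UP if cand["candidate_class"] == CLASS_HIGH else DIRECTION_DOWN
        gene_wells = deconv_scored[
            (deconv_scored["gene_symbol"] == gene)
            & (deconv_scored["role"] == "sample")
        ]
        calls = []
        for d in (1, 2, 3, 4):
            folds = gene_wells.loc[gene_wells["duplex_index"] == d, "fold_ecad"]
            if len(folds) < 2:
                raise ValidationError(
                    f"gene {gene!r} duplex {d}: fewer than 2 deconvolution wells"
                )
            calls.append(
                duplex_activity(
                    folds, mock_folds, direction, config,
                    gene_symbol=gene, duplex_index=d,
                )
            )
        n_active, validated = validate_gene(calls, config)
        trail = list(cand["filter_trail"])

        if cand.get("seed_flagged_pool", False):
            flag = SeedFlag(
                gene_symbol=gene,
                matching_duplexes=seed_match_sets.get(gene, frozenset({1})),
                matched_family="miR-200",
                exclusion=True,
            )
            active_map = {c.duplex_index: c.active for c in calls}
            excluded = seed_exclusion(flag, active_map, config.min_active_duplexes)
            # rescue overrides the pool-stage seed failure
            trail = [
                (name, (not excluded) if name == STEP_SEED else ok)
                for name, ok in trail
            ]
            validated = validated and not excluded
        trail.append((STEP_DECONV, validated))

        verdict_rows.append(
            {
                "gene_symbol": gene,
                "candidate_class": cand["candidate_class"],
                "n_active": n_active,
                "validated": validated,
                "filter_trail": trail,
            }
        )
        call_rows.extend(
            {
                "gene_symbol": c.gene_symbol,
                "duplex_index": c.duplex_index,
                "fold_ecad": c.fold_ecad,
                "p_value": c.p_value,
                "direction": c.direction,
                "active": c.active,
            }
            for c in calls
        )
    return pd.DataFrame(verdict_rows), pd.DataFrame(call_rows)


def classify_regulators(verdicts: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split validated genes into (negative, positive) E-cadherin regulators.

    Negative regulators are validated Ecad-High genes (knockdown raises
    membrane E-cadherin, siZEB1-like); positive regulators are validated
    Ecad-Low genes (siCDH1-like). Lists are disjoint and alphabetical.
    """
    validated = verdicts[verdicts["validated"].astype(bool)]
    by_class = validated.groupby("gene_symbol")["candidate_class"].nunique()
    both = by_class[by_class > 1]
    if len(both):
        raise ValidationError(
            f"genes in both candidate classes (upstream bug): {sorted(both.index)}"
        )
    negative = sorted(validated.loc[validated["candidate_class"] == CLASS_HIGH, "gene_symbol"])
    positive = sorted(validated.loc[validated["candidate_class"] == CLASS_LOW, "gene_symbol"])
    return negative, positive
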