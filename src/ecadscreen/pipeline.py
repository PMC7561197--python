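"""End-to-end orchestration of the screen analysis.

Ties together normalization, viability, seed analysis and hit calling into
the published funnel: duplicate-plate averaging -> fold-to-mock -> robust Z
-> low-count exclusion -> Ecad binning -> RPKM filter -> miR-200 seed
filter -> deconvolution 2-of-4 validation -> regulator lists, with a
per-gene audit trail and per-step funnel counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import hits, normalize, viability
from .config import DEFAULT_CONFIG, ScreenConfig
from .layouts import ROLE_MOCK, ROLE_SAMPLE
from .seeds import mir200_family, scan_duplex_table


@dataclass
class ScreenResults:
    """Everything the analysis produces, ready for reporting."""

    report: pd.DataFrame
    verdicts: pd.DataFrame
    duplex_calls: pd.DataFrame
    negative_regulators: list[str]
    positive_regulators: list[str]
    funnel: dict[str, float]
    scored_primary: pd.DataFrame
    scored_deconv: pd.DataFrame | None = None


def _final_class(row) -> str:
    if bool(row["validated"]) and row["candidate_class"] == hits.CLASS_HIGH:
        return "negative_regulator"
    if bool(row["validated"]) and row["candidate_class"] == hits.CLASS_LOW:
        return "positive_regulator"
    if row["pro_survival"]:
        return "pro_survival"
    if row["anti_proliferative"]:
        return "anti_proliferative"
    return "none"


def analyze_screen(
    primary_a: pd.DataFrame,
    primary_b: pd.DataFrame,
    expression: pd.DataFrame,
    seed_flags: pd.DataFrame | None = None,
    deconv_a: pd.DataFrame | None = None,
    deconv_b: pd.DataFrame | None = None,
    config: ScreenConfig = DEFAULT_CONFIG,
    on_missing_expression: str = "error",
) -> ScreenResults:
    """Run the full analysis on primary (and optional deconvolution) tables.

    Without deconvolution tables the funnel stops after the primary
    cascade (no gene validates). Seed-flagged Ecad-High genes remain
    eligible for deconvolution so the seed rescue can fire.
    """
    scored = normalize.score_screen(primary_a, primary_b)
    genes = normalize.gene_scores(scored)

    averaged_mocks = scored[scored["role"] == ROLE_MOCK]
    cutoff, fov_raw = viability.fov_cutoff(averaged_mocks["fov_used"], config)
    fov_mean = float(averaged_mocks["fov_used"].mean())
    fov_sd = float(averaged_mocks["fov_used"].std(ddof=1))

    via_rows = []
    for _, g in genes.iterrows():
        ecad_bin = hits.bin_ecad(g["fold_ecad"], config)
        call = viability.call_viability(
            g["gene_symbol"], g["fold_count"], g["cell_count"], g["fov_used"],
            ecad_bin, cutoff, config,
        )
        via_rows.append(
            {
                "gene_symbol": call.gene_symbol,
                "cv_bin": call.cv_bin,
                "pro_survival": call.pro_survival,
                "anti_proliferative": call.anti_proliferative,
                "fov_used": call.fov_used,
            }
        )
    via = pd.DataFrame(via_rows)

    candidates = hits.primary_candidates(
        genes, via, expression, seed_flags, config, on_missing_expression
    )

    eligible = candidates[candidates["candidate"] | candidates["seed_flagged_pool"]]
    scored_deconv = None
    if deconv_a is not None and deconv_b is not None and len(eligible):
        scored_deconv = normalize.score_screen(deconv_a, deconv_b)
        deconv_genes = set(
            scored_deconv.loc[scored_deconv["role"] == ROLE_SAMPLE, "gene_symbol"]
        )
        eligible = eligible[eligible["gene_symbol"].isin(deconv_genes)]
        verdicts, duplex_calls = hits.deconvolve_candidates(
            eligible, scored_deconv, seed_flags, config
        )
    else:
        verdicts = pd.DataFrame(
            columns=["gene_symbol", "candidate_class", "n_active", "validated", "filter_trail"]
        )
        duplex_calls = pd.DataFrame(
            columns=["gene_symbol", "duplex_index", "fold_ecad", "p_value", "direction", "active"]
        )
    negative, positive = hits.classify_regulators(verdicts)

    # ------------------------------------------------------------- report
    report = candidates.merge(via, on="gene_symbol", how="left")
    report = report.merge(
        expression[["gene_symbol", "rpkm"]], on="gene_symbol", how="left"
    )
    v = verdicts[["gene_symbol", "n_active", "validated", "filter_trail"]].rename(
        columns={"filter_trail": "trail_final"}
    )
    report = report.merge(v, on="gene_symbol", how="left")
    report["validated"] = (
        report["validated"].astype(object).where(report["validated"].notna(), False).astype(bool)
    )
    report["n_active"] = report["n_active"].astype(float).fillna(0).astype(int)
    report["filter_trail"] = [
        tf if isinstance(tf, list) else t
        for tf, t in zip(report["trail_final"], report["filter_trail"])
    ]
    report = report.drop(columns=["trail_final"])
    if seed_flags is not None and len(seed_flags):
        sm = dict(zip(seed_flags["gene_symbol"], seed_flags["seed_matched"].astype(bool)))
        report["seed_matched"] = report["gene_symbol"].map(sm).fillna(False)
    else:
        report["seed_matched"] = False
    report["final_class"] = [_final_class(r) for _, r in report.iterrows()]
    report = report.sort_values("gene_symbol").reset_index(drop=True)

    trail_has = lambda trail, step, ok: any(n == step and p is ok for n, p in trail)
    funnel = {
        "n_genes": int(len(genes)),
        "n_lc_excluded": int(sum(trail_has(t, hits.STEP_LC, False) for t in report["filter_trail"])),
        "n_ecad_high": int((report["ecad_bin"] == hits.ECAD_HIGH).sum()),
        "n_ecad_low": int((report["ecad_bin"] == hits.ECAD_LOW).sum()),
        "n_ecad_nc": int((report["ecad_bin"] == hits.ECAD_NC).sum()),
        "n_rpkm_removed": int(sum(trail_has(t, hits.STEP_RPKM, False) for t in report["filter_trail"])),
        "n_seed_flagged": int(report["seed_matched"].sum()),
        "n_deconvolved": int(len(verdicts)),
        "n_validated": int(len(negative) + len(positive)),
        "n_negative_regulators": int(len(negative)),
        "n_positive_regulators": int(len(positive)),
        "n_pro_survival": int(report["pro_survival"].sum()),
        "n_anti_proliferative": int(report["anti_proliferative"].sum()),
        "fov_cutoff": int(cutoff),
        "fov_cutoff_raw": float(fov_raw),
        "mock_fov_mean": fov_mean,
        "mock_fov_sd": fov_sd,
    }
    return ScreenResults(
        report=report,
        verdicts=verdicts,
        duplex_calls=duplex_calls,
        negative_regulators=negative,
        positive_regulators=positive,
        funnel=funnel,
        scored_primary=scored,
        scored_deconv=scored_deconv,
    )


def run_synthetic_screen(
    gene_specs: Sequence,
    config: ScreenConfig = DEFAULT_CONFIG,
    noise_sd: float = 0.1,
    seed: int = 0,
    frac_low_expression: float = 0.0,
    reps_per_duplex: int = 3,
    protect_regulators_expression: bool = True,
):
    """Generate a full synthetic screen and analyze it end to end.

    Builds the primary duplicate plates, per-gene 4-duplex sets (seed
    carriers where the spec plants them), the RPKM table, runs the primary
    cascade, then generates and analyzes the deconvolution screen for the
    eligible candidates. Returns ``(results, truth)``.
    """
    from . import simulate
    from .simulate import derive_seed, make_duplex_set

    gene_specs = list(gene_specs)
    primary_a, primary_b, _, truth = simulate.make_screen(
        gene_specs, config, noise_sd, seed=derive_seed(seed, "primary")
    )

    family = mir200_family(config)
    family_seeds = sorted(family.seeds)
    duplex_tables = []
    for spec in gene_specs:
        carriers = sorted(spec.seed_carrier_duplexes)
        n_matching = len(carriers)
        duplex_tables.append(
            make_duplex_set(
                spec.gene_symbol,
                family_seed=family_seeds if n_matching else None,
                n_matching=n_matching,
                seed=derive_seed(seed, "duplexes"),
                config=config,
            )
        )
    duplex_table = pd.concat(duplex_tables, ignore_index=True)
    seed_flags = scan_duplex_table(duplex_table, [family], config)

    effect_genes = {
        s.gene_symbol
        for s in gene_specs
        if s.effect_class in ("ecad_up", "ecad_down")
    }
    expression = simulate.make_expression_table(
        [s.gene_symbol for s in gene_specs],
        frac_low=frac_low_expression,
        seed=derive_seed(seed, "rpkm"),
        always_expressed=effect_genes if protect_regulators_expression else (),
    )

    # primary pass to find who gets deconvolved
    primary_only = analyze_screen(
        primary_a, primary_b, expression, seed_flags, config=config
    )
    eligible_genes = sorted(
        primary_only.report.loc[
            primary_only.report["candidate"] | primary_only.report["seed_flagged_pool"],
            "gene_symbol",
        ]
    )
    spec_by_name = {s.gene_symbol: s for s in gene_specs}
    deconv_specs = [spec_by_name[g] for g in eligible_genes]
    if deconv_specs:
        deconv_a, deconv_b, _, _ = simulate.make_deconvolution_screen(
            deconv_specs, config, noise_sd,
            seed=derive_seed(seed, "deconvolution"),
            reps_per_duplex=reps_per_duplex,
        )
    else:
        deconv_a = deconv_b = None
    results = analyze_screen(
        primary_a, primary_b, expression, seed_flags,
        deconv_a, deconv_b, config=config,
    )
    return results, truth
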