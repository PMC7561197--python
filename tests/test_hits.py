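"""Ecad binning, the primary filter cascade, duplex activity, 2-of-4 validation."""

import math

import numpy as np
import pandas as pd
import pytest

from ecadscreen.config import ScreenConfig
from ecadscreen.errors import ValidationError
from ecadscreen.hits import (
    CLASS_HIGH,
    CLASS_LOW,
    DuplexCall,
    STEP_ECAD,
    STEP_LC,
    STEP_RPKM,
    STEP_SEED,
    bin_ecad,
    classify_regulators,
    duplex_activity,
    primary_candidates,
    validate_gene,
)

CFG = ScreenConfig()


class TestBinEcad:
    @pytest.mark.parametrize(
        "fold,expected",
        [
            (1.6, "High"),  # the printed cutoff is itself in the bin
            (0.2, "Low"),
            (1.0, "NC"),
            (2.5, "High"),
            (0.0, "Low"),
            (0.21, "NC"),
            (1.59, "NC"),
        ],
    )
    def test_boundaries(self, fold, expected):
        assert bin_ecad(fold, CFG) == expected

    def test_negative_fold_rejected(self):
        with pytest.raises(ValidationError):
            bin_ecad(-0.5, CFG)


def _gene_scores(rows):
    return pd.DataFrame(
        rows, columns=["gene_symbol", "fold_ecad", "fold_count", "z_ecad"]
    )


def _viability(genes, lc=()):
    return pd.DataFrame(
        {
            "gene_symbol": genes,
            "cv_bin": ["LC" if g in lc else "CV1" for g in genes],
        }
    )


class TestPrimaryCandidates:
    def setup_method(self):
        # ten genes, one per fate, thresholds straddled deliberately
        self.scores = _gene_scores(
            [
                ("LCGENE", 2.0, 0.3, 5.0),    # excluded at LC despite high Ecad
                ("HIGH1", 1.8, 1.0, 6.0),     # survives as ecad_high
                ("HIGH2", 1.6, 0.9, 5.2),     # boundary High, survives
                ("LOW1", 0.1, 1.0, -2.0),     # survives as ecad_low
                ("LOW2", 0.2, 1.1, -1.9),     # boundary Low, survives
                ("NCGENE", 1.0, 1.0, 0.0),    # dropped at Ecad bin
                ("RPKMHI", 1.8, 1.0, 6.0),    # dropped at RPKM (0.5 < 1)
                ("RPKMLO", 0.15, 1.0, -2.0),  # Low candidate dropped at RPKM
                ("SEEDY", 2.2, 1.0, 7.0),     # High candidate with a seed carrier
                ("NULLG", 0.9, 1.0, 0.1),     # dropped at Ecad bin
            ]
        )
        genes = list(self.scores["gene_symbol"])
        self.via = _viability(genes, lc={"LCGENE"})
        self.expr = pd.DataFrame(
            {
                "gene_symbol": genes,
                "rpkm": [10, 10, 10, 10, 10, 10, 0.5, 0.5, 10, 10],
            }
        )
        self.flags = pd.DataFrame(
            {
                "gene_symbol": genes,
                "seed_matched": [g == "SEEDY" for g in genes],
                "matching_duplexes": ["1" if g == "SEEDY" else "" for g in genes],
            }
        )

    def test_survivors_match_hand_enumeration(self):
        out = primary_candidates(self.scores, self.via, self.expr, self.flags, CFG)
        survivors = set(out.loc[out["candidate"], "gene_symbol"])
        assert survivors == {"HIGH1", "HIGH2", "LOW1", "LOW2"}
        by_gene = out.set_index("gene_symbol")
        assert by_gene.loc["HIGH1", "candidate_class"] == CLASS_HIGH
        assert by_gene.loc["LOW2", "candidate_class"] == CLASS_LOW

    def test_trail_is_order_faithful(self):
        """A gene failing an early filter is never evaluated by a later one."""
        out = primary_candidates(self.scores, self.via, self.expr, self.flags, CFG)
        trail = dict(out.set_index("gene_symbol")["filter_trail"])
        assert trail["LCGENE"] == [(STEP_LC, False)]
        assert trail["NCGENE"] == [(STEP_LC, True), (STEP_ECAD, False)]
        assert trail["RPKMHI"] == [
            (STEP_LC, True), (STEP_ECAD, True), (STEP_RPKM, False),
        ]
        assert trail["SEEDY"] == [
            (STEP_LC, True), (STEP_ECAD, True), (STEP_RPKM, True), (STEP_SEED, False),
        ]

    def test_seed_filter_applies_to_high_candidates_only(self):
        out = primary_candidates(self.scores, self.via, self.expr, self.flags, CFG)
        by_gene = out.set_index("gene_symbol")
        # a Low candidate's trail never contains the seed step
        assert all(n != STEP_SEED for n, _ in by_gene.loc["LOW1", "filter_trail"])

    def test_missing_expression_fails_loudly(self):
        expr = self.expr[self.expr["gene_symbol"] != "HIGH1"]
        with pytest.raises(ValidationError, match="HIGH1"):
            primary_candidates(self.scores, self.via, expr, self.flags, CFG)


def welch_free_t_and_p(x, m):
    """Independent pooled-variance one-tailed t-test, computed from scratch."""
    from scipy.stats import t as tdist

    nx, nm = len(x), len(m)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (nm - 1) * np.var(m, ddof=1)) / (nx + nm - 2)
    t = (np.mean(x) - np.mean(m)) / math.sqrt(sp2 * (1 / nx + 1 / nm))
    return t, float(tdist.sf(t, nx + nm - 2))


class TestDuplexActivity:
    def test_strong_up_duplex_is_active(self):
        x = [1.9, 2.1, 2.0]
        m = [1.0, 0.95, 1.05]
        call = duplex_activity(x, m, "up", CFG)
        _, p_expected = welch_free_t_and_p(x, m)
        assert call.p_value == pytest.approx(p_expected, rel=1e-9)
        assert p_expected < 1e-4
        assert call.fold_ecad == pytest.approx(2.0)
        assert call.active

    def test_null_duplex_not_active(self):
        m = [1.0, 0.95, 1.05, 0.98, 1.02]
        call = duplex_activity(m, m, "up", CFG)
        assert not call.active

    def test_significant_but_subthreshold_fold_not_active(self):
        """A consistent small shift fails the fold gate despite a tiny p."""
        x = [1.30, 1.31, 1.29, 1.30, 1.30]
        m = [1.00, 1.01, 0.99, 1.00, 1.00]
        call = duplex_activity(x, m, "up", CFG)
        assert call.p_value < 0.001
        assert not call.active

    def test_down_direction(self):
        call = duplex_activity([0.1, 0.12, 0.08], [1.0, 0.95, 1.05], "down", CFG)
        assert call.active
        call2 = duplex_activity([0.5, 0.52, 0.48], [1.0, 0.95, 1.05], "down", CFG)
        assert not call2.active  # 0.5 does not clear the 0.2 Low threshold

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValidationError):
            duplex_activity([2.0], [1.0, 1.0], "up", CFG)


def _calls(actives):
    return [
        DuplexCall("G", d, 2.0 if a else 1.0, 0.01 if a else 0.5, "up", a)
        for d, a in zip((1, 2, 3, 4), actives)
    ]


class TestValidateGene:
    @pytest.mark.parametrize(
        "actives,expected",
        [
            ((True, True, False, False), True),   # 2 of 4 validates
            ((True, False, False, False), False),  # 1 of 4 does not
            ((True, True, True, True), True),
            ((False, False, False, False), False),
        ],
    )
    def test_two_of_four_rule(self, actives, expected):
        n, validated = validate_gene(_calls(actives), CFG)
        assert validated == expected
        assert n == sum(actives)

    def test_monotone_in_active_duplexes(self):
        """Adding an active duplex never un-validates a gene."""
        for base in range(16):
            actives = [bool(base & (1 << i)) for i in range(4)]
            _, v1 = validate_gene(_calls(actives), CFG)
            for i in range(4):
                if not actives[i]:
                    more = list(actives)
                    more[i] = True
                    _, v2 = validate_gene(_calls(more), CFG)
                    assert v2 >= v1

    def test_wrong_call_count_rejected(self):
        with pytest.raises(ValidationError):
            validate_gene(_calls((True, True, False, False))[:3], CFG)


class TestClassifyRegulators:
    def test_classes_split_and_sorted(self):
        verdicts = pd.DataFrame(
            {
                "gene_symbol": ["B", "A", "C", "D", "E"],
                "candidate_class": [CLASS_HIGH, CLASS_HIGH, CLASS_LOW, CLASS_LOW, CLASS_LOW],
                "validated": [True, True, True, True, False],
            }
        )
        neg, pos = classify_regulators(verdicts)
        assert neg == ["A", "B"]
        assert pos == ["C", "D"]

    def test_empty_verdicts(self):
        verdicts = pd.DataFrame(columns=["gene_symbol", "candidate_class", "validated"])
        assert classify_regulators(verdicts) == ([], [])

    def test_gene_in_both_classes_is_an_error(self):
        verdicts = pd.DataFrame(
            {
                "gene_symbol": ["A", "A"],
                "candidate_class": [CLASS_HIGH, CLASS_LOW],
                "validated": [True, True],
            }
        )
        with pytest.raises(ValidationError, match="both"):
            classify_regulators(verdicts)
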