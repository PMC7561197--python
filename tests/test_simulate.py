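"""Generator contracts: determinism, planted effects, ground-truth sufficiency."""

import numpy as np
import pandas as pd
import pytest

from ecadscreen.config import ScreenConfig
from ecadscreen.errors import ValidationError
from ecadscreen.simulate import (
    EffectSpec,
    anti_proliferative_gene,
    derive_seed,
    ecad_up_gene,
    make_expression_table,
    make_field_image,
    make_screen,
    null_gene,
    toxic_gene,
)

CFG = ScreenConfig()


class TestEffectSpec:
    def test_class_contracts_enforced(self):
        with pytest.raises(ValidationError):
            EffectSpec("G", "ecad_up", ecad_fold_effect=1.2).validate_against(CFG)
        with pytest.raises(ValidationError):
            EffectSpec("G", "toxic", count_fold_effect=0.8).validate_against(CFG)
        with pytest.raises(ValidationError):
            EffectSpec("G", "anti_proliferative", count_fold_effect=0.9).validate_against(CFG)

    def test_active_duplexes_include_carriers_first(self):
        spec = EffectSpec(
            "G", "ecad_up", ecad_fold_effect=2.0,
            seed_carrier_duplexes=frozenset({3}), n_active_duplexes=2,
        )
        assert spec.active_duplexes == {1, 3}


class TestFieldImages:
    def test_byte_identical_under_same_seed(self):
        a, _ = make_field_image(10, 0.5, seed=7, shape=(256, 256))
        b, _ = make_field_image(10, 0.5, seed=7, shape=(256, 256))
        assert np.array_equal(a.channel1, b.channel1)
        assert np.array_equal(a.channel2, b.channel2)

    def test_zero_lambda_plants_no_fibre_structures(self):
        img, truth = make_field_image(20, 0.0, seed=1, shape=(256, 256))
        assert truth.n_fibres == 0
        # channel 2 is background + noise only: no pixel anywhere near fibre brightness
        assert img.channel2.max() < 600

    def test_zero_cells_gives_background_only(self):
        img, truth = make_field_image(0, 1.0, seed=1, shape=(128, 128))
        assert len(truth.nucleus_centres) == 0
        assert truth.n_fibres == 0
        assert img.channel1.max() < 600

    def test_truth_counts_match_image_content(self):
        img, truth = make_field_image(15, 0.0, seed=9, shape=(256, 256))
        assert len(truth.nucleus_centres) == 15

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValidationError):
            make_field_image(500, 0.0, seed=0, shape=(128, 128), min_separation=40)


class TestScreenTables:
    def test_all_null_screen_mock_normalized_mean_near_one(self):
        """100 null genes at noise sd 0.1: mean mock-normalized Ecad fold in [0.9, 1.1]."""
        specs = [null_gene(f"N{i:03d}") for i in range(100)]
        a, b, layouts, truth = make_screen(specs, CFG, noise_sd=0.1, seed=42)
        from ecadscreen.normalize import score_screen

        scored = score_screen(a, b)
        samples = scored[scored["role"] == "sample"]
        assert len(samples) == 100
        assert 0.9 <= samples["fold_ecad"].mean() <= 1.1

    def test_planted_ecad_up_gene_exceeds_high_threshold(self):
        specs = [ecad_up_gene("UPG", fold=2.0)] + [null_gene(f"N{i}") for i in range(30)]
        a, b, _, _ = make_screen(specs, CFG, noise_sd=0.1, seed=1)
        from ecadscreen.normalize import score_screen

        scored = score_screen(a, b)
        up = scored[scored["gene_symbol"] == "UPG"]
        assert up["fold_ecad"].iloc[0] >= CFG.fold_high

    def test_siplk1_wells_fall_below_cv2(self):
        """The toxicity control loses more than half the mock cell count."""
        specs = [null_gene(f"N{i}") for i in range(10)]
        a, b, _, _ = make_screen(specs, CFG, noise_sd=0.1, seed=5)
        from ecadscreen.normalize import score_screen

        scored = score_screen(a, b)
        plk1 = scored[scored["role"] == "siPLK1"]
        assert (plk1["fold_count"] < CFG.cv2_min).all()

    def test_sicdh1_raw_score_is_zero(self):
        specs = [null_gene("N0")]
        a, _, _, _ = make_screen(specs, CFG, seed=2)
        assert (a.loc[a["role"] == "siCDH1", "ecad_raw"] == 0).all()

    def test_mock_wells_need_about_20_fields(self):
        specs = [null_gene(f"N{i}") for i in range(10)]
        a, _, _, _ = make_screen(specs, CFG, noise_sd=0.1, seed=8)
        mock_fov = a.loc[a["role"] == "mock", "fov_used"]
        assert 18 <= mock_fov.mean() <= 22

    def test_deterministic_given_seed(self):
        specs = [null_gene(f"N{i}") for i in range(5)]
        a1, b1, _, _ = make_screen(specs, CFG, seed=3)
        a2, b2, _, _ = make_screen(specs, CFG, seed=3)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_too_many_genes_rejected(self):
        from ecadscreen.errors import LayoutError

        specs = [null_gene(f"N{i}") for i in range(321)]
        # 321 genes spill onto a second plate; that is allowed.
        a, _, layouts, _ = make_screen(specs, CFG, seed=1)
        assert len(layouts) == 2
        # duplicate symbols are not
        with pytest.raises(ValidationError):
            make_screen([null_gene("X"), null_gene("X")], CFG, seed=1)


class TestExpressionTable:
    def test_frac_low_zero_all_expressed(self):
        t = make_expression_table([f"G{i}" for i in range(10)], frac_low=0.0, seed=1)
        assert (t["rpkm"] >= 1).all()

    def test_frac_low_one_all_below(self):
        t = make_expression_table([f"G{i}" for i in range(10)], frac_low=1.0, seed=1)
        assert (t["rpkm"] < 1).all()

    def test_floor_arithmetic(self):
        t = make_expression_table([f"G{i}" for i in range(10)], frac_low=0.2, seed=1)
        assert (t["rpkm"] < 1).sum() == 2

    def test_protected_genes_stay_expressed(self):
        genes = [f"G{i}" for i in range(20)]
        t = make_expression_table(genes, frac_low=0.5, seed=1, always_expressed=genes[:10])
        by = t.set_index("gene_symbol")["rpkm"]
        assert (by[genes[:10]] >= 1).all()
        assert (by < 1).sum() == 10

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            make_expression_table(["G1"], frac_low=1.5)


def test_derived_seeds_are_stable_and_distinct():
    s1 = derive_seed(1, "plate", "A01")
    assert s1 == derive_seed(1, "plate", "A01")
    assert s1 != derive_seed(1, "plate", "A02")
    assert s1 != derive_seed(2, "plate", "A01")
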