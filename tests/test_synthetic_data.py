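"""Generator correctness: determinism, ground truth, and round trips."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lungquant.expression import relative_expression
from lungquant.mechanics import PVLoop, fit_constant_phase, pv_metrics
from lungquant.morphometry import mli_for_image
from lungquant.synthetic_data import (
    AIRSPACE_RGB,
    ChordSummary,
    CohortDesign,
    NoAirspaceError,
    ParenchymaParams,
    derive_seed,
    generate_cohort,
    generate_ct_table,
    generate_impedance,
    generate_parenchyma_image,
    generate_pv_loop,
    measure_true_chords,
    split_group_label,
)
from conftest import rle_chords

SMALL = dict(image_width=320, image_height=240)


class TestParenchyma:
    def test_fixed_seed_is_bit_identical(self):
        a_img, a_gt = generate_parenchyma_image(ParenchymaParams(seed=1, **SMALL))
        b_img, b_gt = generate_parenchyma_image(ParenchymaParams(seed=1, **SMALL))
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert np.array_equal(a_gt.airspace_mask, b_gt.airspace_mask)
        c_img, _ = generate_parenchyma_image(ParenchymaParams(seed=2, **SMALL))
        assert not np.array_equal(a_img.pixels, c_img.pixels)

    def test_noiseless_white_pixels_equal_ground_truth_mask(self):
        p = ParenchymaParams(noise_sd=0.0, macrophage_count=0, speckle_count=0,
                             seed=5, **SMALL)
        img, gt = generate_parenchyma_image(p)
        white = np.all(img.pixels == AIRSPACE_RGB, axis=-1)
        assert np.array_equal(white, gt.airspace_mask)

    def test_recorded_chord_matches_independent_rle_oracle(self):
        p = ParenchymaParams(target_cell_diameter=33.0, noise_sd=0.0, seed=3, **SMALL)
        _, gt = generate_parenchyma_image(p)
        oracle = np.mean(rle_chords(gt.airspace_mask)) / p.px_per_micron
        assert gt.true_mean_airspace_chord == pytest.approx(oracle, rel=0.10)

    def test_macrophages_are_dark_and_inside_airspace(self):
        from lungquant.synthetic_data import MACROPHAGE_RGB

        p = ParenchymaParams(macrophage_count=3, noise_sd=0.0, seed=7, **SMALL)
        img, gt = generate_parenchyma_image(p)
        blob = np.all(img.pixels == MACROPHAGE_RGB, axis=-1)
        assert blob.any()
        assert gt.airspace_mask[blob].all()  # blobs lie entirely in airspace
        lum = np.array([0.299, 0.587, 0.114])
        assert MACROPHAGE_RGB @ lum < np.array([214, 143, 168]) @ lum  # darker than tissue

    def test_speckles_are_small_white_components_on_tissue(self):
        from scipy import ndimage

        p = ParenchymaParams(speckle_count=5, noise_sd=0.0, seed=11, **SMALL)
        img, gt = generate_parenchyma_image(p)
        white = np.all(img.pixels == AIRSPACE_RGB, axis=-1)
        extra = white & ~gt.airspace_mask
        labels, n = ndimage.label(extra, structure=np.ones((3, 3)))
        assert n >= 1
        areas = np.bincount(labels.ravel())[1:]
        assert (areas < 500).all()

    def test_oversized_macrophage_rejected(self):
        with pytest.raises(ValueError, match="macrophage_diameter"):
            generate_parenchyma_image(
                ParenchymaParams(macrophage_count=1, macrophage_diameter=40.0,
                                 target_cell_diameter=30.0, **SMALL))

    @pytest.mark.parametrize("bad", [dict(image_width=0), dict(septal_thickness=-1.0),
                                     dict(target_cell_diameter=2.0, septal_thickness=3.0)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ParenchymaParams(**{**SMALL, **bad})


class TestChordScan:
    def test_full_width_band_closed_form(self):
        mask = np.zeros((30, 100), dtype=bool)
        mask[10:20] = True
        s = measure_true_chords(mask, px_per_micron=2.0)
        assert s.count == 10
        assert s.mean_um == pytest.approx(100 / 2.0)

    def test_all_tissue_signals_no_chords(self):
        with pytest.raises(NoAirspaceError):
            measure_true_chords(np.zeros((5, 5), dtype=bool), 2.764)

    def test_matches_rle_oracle_on_random_masks(self, random_masks):
        for mask in random_masks:
            lengths = rle_chords(mask)
            if not lengths:
                continue
            s = measure_true_chords(mask, px_per_micron=1.0)
            assert s.count == len(lengths)
            assert s.mean_um == pytest.approx(np.mean(lengths))


class TestPVLoopGenerator:
    P = np.linspace(0.0, 30.0, 16)

    def test_degenerate_loop_has_zero_area(self):
        loop = generate_pv_loop(1.0, 0.9, 0.12, self.P, hysteresis_offset=0.0,
                                noise_sd=0.0)
        assert np.array_equal(loop.volume_inflation, loop.volume_deflation)
        assert pv_metrics(loop).area == pytest.approx(0.0, abs=1e-12)

    def test_volume_at_zero_pressure_is_A_minus_B(self):
        loop = generate_pv_loop(1.2, 0.8, 0.1, self.P, noise_sd=0.0)
        assert loop.volume_deflation[0] == pytest.approx(1.2 - 0.8, abs=1e-12)

    def test_hysteresis_loop_closes_at_endpoints(self):
        loop = generate_pv_loop(1.0, 0.9, 0.12, self.P, hysteresis_offset=0.08,
                                noise_sd=0.0)
        assert loop.volume_inflation[0] == pytest.approx(loop.volume_deflation[0])
        assert loop.volume_inflation[-1] == pytest.approx(loop.volume_deflation[-1])
        assert pv_metrics(loop).area > 0

    def test_round_trip_recovers_static_compliance(self):
        A, B, K = 1.0, 0.9, 0.12
        loop = generate_pv_loop(A, B, K, self.P, noise_sd=0.0)
        met = pv_metrics(loop, cst_pressure=5.0)
        assert met.Cst == pytest.approx(B * K * np.exp(-K * 5.0), rel=1e-6)

    def test_non_monotone_pressures_rejected(self):
        with pytest.raises(ValueError):
            generate_pv_loop(1.0, 0.9, 0.12, np.array([0.0, 10.0, 5.0, 30.0]))

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_pv_loop(0.8, 0.9, 0.12, self.P)  # A <= B


class TestImpedanceGenerator:
    def test_equal_damping_and_elastance_gives_alpha_half(self):
        from lungquant.mechanics import constant_phase_alpha

        assert constant_phase_alpha(7.0, 7.0) == pytest.approx(0.5)

    def test_single_frequency_closed_form(self):
        f = 5.0
        G, H = 4.0, 20.0
        alpha = (2 / np.pi) * np.arctan(H / G)
        spec = generate_impedance(0.3, 0.0, G, H, [f], noise_sd=0.0)
        w = 2 * np.pi * f
        assert spec.Z[0].real == pytest.approx(0.3 + G / w**alpha)
        assert spec.Z[0].imag == pytest.approx(-H / w**alpha)

    def test_round_trip_recovers_parameters(self):
        spec = generate_impedance(0.3, 0.005, 4.0, 20.0, np.linspace(1, 20, 13),
                                  noise_sd=0.0)
        fit = fit_constant_phase(spec)
        for got, true in ((fit.Rn, 0.3), (fit.Iaw, 0.005), (fit.G, 4.0), (fit.H, 20.0)):
            assert got == pytest.approx(true, rel=1e-6)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            generate_impedance(0.3, 0.005, 4.0, 20.0, [0.0, 1.0])


class TestCtTable:
    animals = pd.DataFrame({
        "animal_id": [f"m{i}" for i in range(4)],
        "group": ["CD-NS", "CD-NS", "VDD-CSE", "VDD-CSE"],
    })

    def test_zero_fold_change_gives_unit_relative_expression(self):
        fc = {"MMP9": {}, "TIMP1": {}, "A1AT": {}}
        ct = generate_ct_table(self.animals, log2fc=fc, ct_noise_sd=0.0)
        rel = relative_expression(ct)
        baseline = {"MMP9": 2.0 ** -(26 - 18), "TIMP1": 2.0 ** -(24 - 18),
                    "A1AT": 2.0 ** -(21 - 18), "RPL13a": 1.0}
        for _, row in rel.iterrows():
            assert row["rel"] == pytest.approx(baseline[row["gene"]])

    def test_programmed_doubling_is_exactly_twofold(self):
        fc = {"MMP9": {"VDD-CSE": 1.0}}
        ct = generate_ct_table(self.animals, log2fc=fc, ct_noise_sd=0.0)
        rel = relative_expression(ct)
        mmp9 = rel[rel["gene"] == "MMP9"].set_index("animal_id")["rel"]
        assert mmp9["m2"] / mmp9["m0"] == pytest.approx(2.0)

    def test_missing_housekeeping_baseline_rejected(self):
        with pytest.raises(ValueError, match="RPL13a"):
            generate_ct_table(self.animals, baseline_ct={"MMP9": 26.0})

    def test_group_mean_recovers_programmed_fold_change(self):
        """Monte-Carlo: mean log2 relative expression ~ programmed log2fc."""
        rng_seeds = range(200)
        animals = pd.DataFrame({
            "animal_id": [f"m{i}" for i in range(22)],
            "group": ["CD-NS"] * 11 + ["VDD-CSE"] * 11,
        })
        fc = {"MMP9": {"VDD-CSE": 1.0}}
        diffs = []
        for s in rng_seeds:
            ct = generate_ct_table(animals, log2fc=fc, ct_noise_sd=0.4, seed=s)
            rel = relative_expression(ct)
            mmp9 = rel[rel["gene"] == "MMP9"]
            log2 = np.log2(mmp9.set_index("animal_id")["rel"])
            diffs.append(log2.iloc[11:].mean() - log2.iloc[:11].mean())
        mean_diff = np.mean(diffs)
        # SE of the replicate mean: sqrt(2*0.4^2*2/11)/sqrt(200) ~ 0.017
        assert mean_diff == pytest.approx(1.0, abs=0.06)


class TestCohortBundle:
    def test_minimal_cohort_layout(self, tmp_path):
        design = CohortDesign(mice_per_group=1, images_per_mouse=1,
                              parenchyma=ParenchymaParams(**SMALL), master_seed=3)
        out = generate_cohort(design, tmp_path / "c")
        assert len(list((out / "images").glob("*.png"))) == 4
        assert len(pd.read_csv(out / "design.csv")) == 4

    def test_same_master_seed_is_byte_identical(self, tmp_path):
        def digest(root: Path) -> dict[str, str]:
            return {p.relative_to(root).as_posix():
                    hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(root.rglob("*")) if p.is_file()}

        design = CohortDesign(mice_per_group=1, images_per_mouse=2,
                              parenchyma=ParenchymaParams(**SMALL), master_seed=9)
        a = generate_cohort(design, tmp_path / "a")
        b = generate_cohort(design, tmp_path / "b")
        assert digest(a) == digest(b)

    def test_group_labels_decompose_into_factors(self):
        assert split_group_label("VDD-CSE") == ("VDD", "CSE")
        assert split_group_label("CD-NS") == ("CD", "NS")
        with pytest.raises(ValueError):
            split_group_label("HFD-NS")

    def test_derived_seeds_are_order_independent(self):
        assert derive_seed(5, 1, 2, 3) == derive_seed(5, 1, 2, 3)
        assert derive_seed(5, 1, 2, 3) != derive_seed(5, 1, 3, 2)
        assert 0 <= derive_seed(5, 7) < 2**31
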