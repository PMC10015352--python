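"""Forward-model tests: absorption composition, two-layer reflectance,
RGB rendering, and the lookup database invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bilicam import forward_model as fm


GRID = fm.DEFAULT_GRID


class TestSpectralCurve:
    def test_validation_rejects_bad_shapes_and_ordering(self):
        with pytest.raises(fm.BilicamError):
            fm.SpectralCurve([400, 500], [1.0])
        with pytest.raises(fm.BilicamError):
            fm.SpectralCurve([500, 400, 600], [1.0, 1.0, 1.0])

    def test_resample_rejects_disjoint_supports(self):
        c = fm.SpectralCurve([400.0, 450.0], [1.0, 1.0])
        with pytest.raises(fm.BilicamError, match="disjoint"):
            c.resample(np.array([600.0, 700.0]))


class TestAbsorption:
    def test_no_absorbers_gives_zero_curve(self):
        params = fm.SkinModelParams(baseline_absorption=fm.SpectralCurve.constant(0.0))
        state = fm.ChromophoreState(0.0, 0.0, 0.0, 0.7)
        for layer in ("epidermis", "dermis"):
            assert np.allclose(fm.absorption_spectrum(state, params, layer).values, 0.0)

    def test_bilirubin_term_is_linear_in_concentration(self):
        params = fm.SkinModelParams()
        base = params.baseline_absorption.values
        s1 = fm.ChromophoreState(100.0, 0.0, 0.0, 0.7)
        s2 = fm.ChromophoreState(200.0, 0.0, 0.0, 0.7)
        a1 = fm.absorption_spectrum(s1, params, "dermis").values - base
        a2 = fm.absorption_spectrum(s2, params, "dermis").values - base
        i460 = int(np.argmin(np.abs(GRID - 460.0)))
        assert a2[i460] == pytest.approx(2.0 * a1[i460], rel=1e-12)
        assert np.allclose(a2, 2.0 * a1)

    # Expected values are an independent term-by-term summation of the three
    # embedded extinction band formulas at five wavelengths (bilirubin 200
    # umol/L, blood 0.02, saturation 0.7, baseline 0.015/mm), frozen here.
    @pytest.mark.parametrize("lam, expected", [
        (420.0, 5.437680796547372),
        (460.0, 2.421609370231841),
        (540.0, 0.7244377071948452),
        (580.0, 0.5247177706022803),
        (650.0, 0.030143324855315897),
    ])
    def test_dermis_absorption_matches_hand_summed_bands(self, lam, expected):
        state = fm.ChromophoreState(200.0, 0.0, 0.02, 0.7)
        curve = fm.absorption_spectrum(state, fm.SkinModelParams(), "dermis")
        value = np.interp(lam, curve.wavelengths_nm, curve.values)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_unknown_layer_rejected(self):
        with pytest.raises(fm.BilicamError, match="unknown skin layer"):
            fm.absorption_spectrum(fm.ChromophoreState(0, 0, 0), fm.SkinModelParams(),
                                   "subcutis")

    def test_state_bounds_enforced(self):
        with pytest.raises(fm.BilicamError):
            fm.ChromophoreState(-1.0, 0.0, 0.0)
        with pytest.raises(fm.BilicamError):
            fm.ChromophoreState(0.0, 1.5, 0.0)


class TestDiffuseReflectance:
    def test_zero_absorption_limit_is_flat_ceiling(self):
        params = fm.SkinModelParams(
            baseline_absorption=fm.SpectralCurve.constant(0.0),
            reduced_scattering=fm.SpectralCurve.constant(2.0))
        R = fm.diffuse_reflectance(fm.ChromophoreState(0, 0, 0), params)
        assert np.allclose(R.values, R.values[0])
        assert R.values[0] > 0.999

    def test_bilirubin_darkens_blue_but_not_red(self):
        lo = fm.diffuse_reflectance(fm.ChromophoreState(0.0, 0.05, 0.02, 0.7))
        hi = fm.diffuse_reflectance(fm.ChromophoreState(300.0, 0.05, 0.02, 0.7))
        i460 = int(np.argmin(np.abs(GRID - 460.0)))
        i650 = int(np.argmin(np.abs(GRID - 650.0)))
        assert hi.values[i460] < lo.values[i460]
        assert hi.values[i650] == pytest.approx(lo.values[i650], rel=0.01)

    def test_matches_fine_grid_evaluation_after_downsampling(self):
        # resolution-refinement oracle: the closed form evaluated on a 10x
        # finer wavelength grid, downsampled, must agree with the 5 nm result
        fine = np.arange(400.0, 700.0 + 1e-9, 0.5)
        params_fine = fm.SkinModelParams(
            reduced_scattering=fm.SpectralCurve(fine, 2.5 * (fine / 500.0) ** (-1.3)),
            baseline_absorption=fm.SpectralCurve.constant(0.015, fine))
        state = fm.ChromophoreState(180.0, 0.06, 0.03, 0.7)
        R_fine = fm.diffuse_reflectance(state, params_fine)
        R = fm.diffuse_reflectance(state, fm.SkinModelParams())
        downsampled = np.interp(GRID, R_fine.wavelengths_nm, R_fine.values)
        assert np.allclose(downsampled, R.values, atol=1e-9)

    def test_negative_scattering_rejected(self):
        with pytest.raises(fm.BilicamError):
            fm.SkinModelParams(reduced_scattering=fm.SpectralCurve.constant(-1.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(melanin=st.floats(0.01, 0.15), blood=st.floats(0.005, 0.05),
           b1=st.floats(0.0, 390.0), delta=st.floats(1.0, 50.0))
    def test_reflectance_monotone_decreasing_in_bilirubin(self, melanin, blood,
                                                          b1, delta):
        i460 = int(np.argmin(np.abs(GRID - 460.0)))
        lo = fm.diffuse_reflectance(fm.ChromophoreState(b1, melanin, blood, 0.7))
        hi = fm.diffuse_reflectance(fm.ChromophoreState(b1 + delta, melanin, blood, 0.7))
        assert hi.values[i460] < lo.values[i460]


class TestRenderRgb:
    def test_unit_reflectance_under_flat_illuminant_is_white(self):
        rgb = fm.render_rgb(fm.SpectralCurve.constant(1.0), fm.flat_illuminant(),
                            fm.default_camera())
        assert np.allclose(rgb, 1.0, atol=1e-12)

    def test_zero_reflectance_is_black(self):
        rgb = fm.render_rgb(fm.SpectralCurve.constant(0.0), fm.flat_illuminant(),
                            fm.default_camera())
        assert np.allclose(rgb, 0.0)

    def test_flat_half_reflectance_with_box_sensitivities(self):
        box = fm.CameraModel("box", tuple(
            fm.SpectralCurve(GRID, ((GRID >= lo) & (GRID < hi)).astype(float))
            for lo, hi in [(580, 700), (480, 580), (400, 480)]))
        rgb = fm.render_rgb(fm.SpectralCurve.constant(0.5), fm.flat_illuminant(), box)
        assert np.allclose(rgb, 0.5, atol=1e-12)

    def test_disjoint_supports_rejected(self):
        ir = fm.Illuminant("ir", fm.SpectralCurve([800.0, 900.0], [1.0, 1.0]))
        with pytest.raises(fm.BilicamError):
            fm.render_rgb(fm.SpectralCurve.constant(1.0), ir, fm.default_camera())

    def test_normalized_illuminant_keeps_white_in_gamut(self):
        for ill in (fm.warm_illuminant(), fm.cool_illuminant()):
            rgb = fm.render_rgb(fm.SpectralCurve.constant(1.0), ill,
                                fm.default_camera())
            assert rgb.max() <= 1.0 and rgb.min() > 0.0


class TestLookupDatabase:
    def test_grid_cartesian_count(self):
        grid = fm.GridSpec(bilirubin_umol_per_L=(0.0, 100.0, 200.0),
                           melanin_fraction=(0.02, 0.1),
                           blood_fraction=(0.01, 0.04))
        db = fm.build_lookup(grid)
        assert len(db.entries) == 12

    def test_rebuild_is_byte_identical(self, tmp_path, small_db):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        small_db.to_csv(a)
        grid = fm.GridSpec(
            bilirubin_umol_per_L=tuple(np.arange(0.0, 400.1, 25.0)),
            melanin_fraction=tuple(np.linspace(0.01, 0.15, 6)),
            blood_fraction=tuple(np.linspace(0.005, 0.05, 4)))
        fm.build_lookup(grid).to_csv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_blue_channel_non_increasing_in_bilirubin(self, small_db):
        for _, slice_df in small_db.entries.groupby(["melanin_fraction",
                                                     "blood_fraction"]):
            ordered = slice_df.sort_values("bilirubin_umol_per_L")["b"].to_numpy()
            assert np.all(np.diff(ordered) <= 1e-12)

    def test_too_few_grid_levels_rejected(self):
        with pytest.raises(fm.BilicamError):
            fm.GridSpec(bilirubin_umol_per_L=(100.0,))

    def test_duplicate_states_rejected(self, small_db):
        dup = fm.LookupDatabase.__new__(fm.LookupDatabase)
        import pandas as pd
        entries = pd.concat([small_db.entries.iloc[:2], small_db.entries.iloc[:1]])
        with pytest.raises(fm.BilicamError, match="duplicate"):
            fm.LookupDatabase(entries, {})

    def test_csv_round_trip(self, tmp_path, small_db):
        path, side = tmp_path / "db.csv", tmp_path / "db.json"
        small_db.to_csv(path, side)
        back = fm.LookupDatabase.from_csv(path, side)
        assert np.allclose(back.rgb, small_db.rgb, atol=1e-9)
        assert back.provenance == small_db.provenance


class TestCameraDiscrimination:
    def test_positive_for_cameras_with_blue_sensitivity(self):
        for cam in (fm.default_camera(), fm.alternate_camera()):
            assert fm.discriminability(cam) > 0.0

    def test_blue_blind_camera_discriminates_poorly(self):
        # channels all in the red-green range: hardly any bilirubin signal
        blind = fm.gaussian_camera("blind", peaks=(660.0, 630.0, 600.0),
                                   sigmas=(20.0, 20.0, 20.0))
        assert fm.discriminability(blind) < 0.1 * fm.discriminability(fm.default_camera())
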