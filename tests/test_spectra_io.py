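"""Spectral CSV dialect, JCAMP import, and data-model invariants."""

import numpy as np
import pytest

from nirtransfer.design import default_training_design
from nirtransfer.spectra_io import (
    DEFAULT_GRID,
    ReferenceTable,
    SpectraSet,
    WavelengthGrid,
    import_jcamp,
    read_spectra_csv,
    write_spectra_csv,
)
from nirtransfer.synthetic import SimScenario, simulate_powder


class TestWavelengthGrid:
    def test_default_instrument_grid_has_1050_channels(self):
        assert DEFAULT_GRID.n_channels == 1050
        assert DEFAULT_GRID.start_nm == 400.0
        assert DEFAULT_GRID.step_nm == 2.0
        assert DEFAULT_GRID.end_nm == 2498.0

    def test_channel_mapping(self):
        g = WavelengthGrid(400.0, 2.0, 5)
        np.testing.assert_allclose(g.wavelengths, [400, 402, 404, 406, 408])

    @pytest.mark.parametrize(
        "kwargs",
        [dict(start_nm=400, step_nm=0, n_channels=5),
         dict(start_nm=400, step_nm=-2, n_channels=5),
         dict(start_nm=400, step_nm=2, n_channels=1)],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WavelengthGrid(**kwargs)

    def test_nonconstant_spacing_rejected(self):
        with pytest.raises(ValueError, match="non-constant spacing"):
            WavelengthGrid.from_wavelengths([400, 402, 405])

    def test_window_indices(self):
        g = WavelengthGrid(400.0, 2.0, 10)
        np.testing.assert_array_equal(g.window_indices(404, 408), [2, 3, 4])


class TestSpectraSetInvariants:
    @pytest.mark.parametrize(
        "mutation",
        ["duplicate_ids", "bad_length", "nan", "inf", "bad_state", "wrong_channels"],
    )
    def test_invariant_violations_rejected(self, small_grid, mutation):
        X = np.ones((3, small_grid.n_channels))
        ids = ["a", "b", "c"]
        kwargs = dict(grid=small_grid, absorbance=X, sample_ids=ids, state="powder")
        if mutation == "duplicate_ids":
            kwargs["sample_ids"] = ["a", "a", "c"]
        elif mutation == "bad_length":
            kwargs["sample_ids"] = ["a", "b"]
        elif mutation == "nan":
            kwargs["absorbance"] = X.copy()
            kwargs["absorbance"][1, 2] = np.nan
        elif mutation == "inf":
            kwargs["absorbance"] = X.copy()
            kwargs["absorbance"][0, 0] = np.inf
        elif mutation == "bad_state":
            kwargs["state"] = "slurry"
        elif mutation == "wrong_channels":
            kwargs["absorbance"] = np.ones((3, 5))
        with pytest.raises(ValueError):
            SpectraSet(**kwargs)

    def test_select_reorders_rows(self, random_spectra):
        sub = random_spectra.select(["s3", "s1"])
        assert sub.sample_ids == ["s3", "s1"]
        np.testing.assert_array_equal(sub.absorbance[0], random_spectra.absorbance[3])

    def test_reference_table_range_checked(self):
        with pytest.raises(ValueError):
            ReferenceTable(["a"], "sucrose", [120.0])
        with pytest.raises(ValueError):
            ReferenceTable(["a"], "sucrose", [-1.0])


class TestCsvRoundTrip:
    def test_read_basic(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,402,404\na,0.1,0.2,0.3\nb,0.4,0.5,0.6\n")
        s = read_spectra_csv(p)
        assert s.n_channels == 3 and s.grid.step_nm == 2.0
        assert s.sample_ids == ["a", "b"]
        np.testing.assert_allclose(s.absorbance, [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])

    def test_nonconstant_spacing_error(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,402,405\na,0.1,0.2,0.3\n")
        with pytest.raises(ValueError, match="non-constant spacing"):
            read_spectra_csv(p)

    @pytest.mark.parametrize(
        "body,match",
        [("a,0.1,0.2\n", "ragged"), ("a,0.1,x,0.3\n", "non-numeric")],
    )
    def test_malformed_rows(self, tmp_path, body, match):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,402,404\n" + body)
        with pytest.raises(ValueError, match=match):
            read_spectra_csv(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,402\na,0.1,0.2\na,0.3,0.4\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra_csv(p)

    def test_expected_grid_mismatch(self, tmp_path, small_grid):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,402,404\na,0.1,0.2,0.3\n")
        with pytest.raises(ValueError, match="grid mismatch"):
            read_spectra_csv(p, expected_grid=small_grid)

    def test_round_trip_bit_exact_on_full_grid(self, tmp_path):
        design = default_training_design()
        spectra, _ = simulate_powder(SimScenario(seed=3, design=design))
        assert spectra.absorbance.shape == (27, 1050)
        treated = spectra.with_matrix(spectra.absorbance, extra_tags=["snv"])
        p = tmp_path / "round.csv"
        write_spectra_csv(treated, p)
        back = read_spectra_csv(p, expected_grid=DEFAULT_GRID)
        assert np.array_equal(back.absorbance, treated.absorbance)  # bit-exact
        assert back.sample_ids == treated.sample_ids
        assert back.state == treated.state
        assert back.pretreatment == ["snv"]

    def test_pretreatment_comment_written(self, tmp_path, random_spectra):
        p = tmp_path / "s.csv"
        write_spectra_csv(random_spectra, p)
        assert "pretreatment" not in p.read_text()
        tagged = random_spectra.with_matrix(
            random_spectra.absorbance, extra_tags=["snv"]
        )
        write_spectra_csv(tagged, p)
        assert "# pretreatment: snv" in p.read_text()


class TestJcamp:
    def test_xypoints(self, tmp_path):
        p = tmp_path / "a.jdx"
        p.write_text(
            "##TITLE=demo\n##JCAMP-DX=4.24\n##XUNITS=NANOMETERS\n"
            "##XYPOINTS=(XY..XY)\n400.0,0.1; 402.0,0.2; 404.0,0.3\n##END=\n"
        )
        s = import_jcamp(p)
        assert s.absorbance.shape == (1, 3)
        np.testing.assert_allclose(s.grid.wavelengths, [400, 402, 404])
        np.testing.assert_allclose(s.absorbance[0], [0.1, 0.2, 0.3])

    def test_decreasing_abscissa_reversed(self, tmp_path):
        p = tmp_path / "a.jdx"
        p.write_text(
            "##TITLE=demo\n##XYPOINTS=(XY..XY)\n"
            "404.0,0.3; 402.0,0.2; 400.0,0.1\n##END=\n"
        )
        s = import_jcamp(p)
        np.testing.assert_allclose(s.grid.wavelengths, [400, 402, 404])
        np.testing.assert_allclose(s.absorbance[0], [0.1, 0.2, 0.3])

    def test_nonconstant_abscissa_error(self, tmp_path):
        p = tmp_path / "a.jdx"
        p.write_text(
            "##TITLE=demo\n##XYPOINTS=(XY..XY)\n400,0.1; 402,0.2; 405,0.3\n##END=\n"
        )
        with pytest.raises(ValueError, match="non-constant"):
            import_jcamp(p)

    def test_xydata_affn(self, tmp_path):
        p = tmp_path / "a.jdx"
        p.write_text(
            "##TITLE=demo\n##XFACTOR=1.0\n##YFACTOR=0.001\n"
            "##XYDATA=(X++(Y..Y))\n400 100 200 300\n406 400 500 600\n##END=\n"
        )
        s = import_jcamp(p)
        np.testing.assert_allclose(
            s.grid.wavelengths, [400, 402, 404, 406, 408, 410]
        )
        np.testing.assert_allclose(s.absorbance[0], [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])

    def test_synthetic_export_import_round_trip(self, tmp_path, rng):
        wl = 400.0 + 2.0 * np.arange(50)
        vals = 0.5 + 0.1 * rng.normal(size=50)
        p = tmp_path / "gen.jdx"
        lines = ["##TITLE=synthetic", "##XYPOINTS=(XY..XY)"]
        lines += [f"{w:.6f},{v:.12f}" for w, v in zip(wl, vals)]
        lines.append("##END=")
        p.write_text("\n".join(lines) + "\n")
        s = import_jcamp(p)
        np.testing.assert_allclose(s.absorbance[0], vals, atol=1e-9)
        np.testing.assert_allclose(s.grid.wavelengths, wl, atol=1e-9)
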