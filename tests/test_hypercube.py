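"""ENVI I/O, radiometric calibration and band management."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocoahsi.errors import (BandMismatchError, CalibrationError,
                             UnsupportedInterleaveError)
from cocoahsi.hypercube import (Hypercube, ReferenceFrames,
                                calibrate_reflectance, exclude_bands,
                                read_envi, to_absorbance, write_envi)


def make_cube(rng, rows=5, cols=6, bands=10, kind="raw"):
    wl = np.linspace(1000, 1100, bands)
    return Hypercube(rng.random((rows, cols, bands)) * 100, wl, kind,
                     {"acquisition id": "t1"})


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    def test_round_trip_identity(self, rng, tmp_path, interleave):
        cube = make_cube(rng)
        path = tmp_path / f"c_{interleave}.hdr"
        write_envi(cube, path, interleave=interleave, dtype=np.float64)
        back = read_envi(path)
        assert np.array_equal(back.data, cube.data)
        assert np.array_equal(back.wavelengths, cube.wavelengths)
        assert back.kind == cube.kind
        assert back.metadata["acquisition id"] == "t1"

    def test_interleaves_read_identically(self, rng, tmp_path):
        cube = make_cube(rng)
        outs = []
        for il in ("bil", "bsq"):
            path = tmp_path / f"x_{il}.hdr"
            write_envi(cube, path, interleave=il, dtype=np.float64)
            outs.append(read_envi(path).data)
        assert np.array_equal(outs[0], outs[1])

    def test_wavelength_count_mismatch_raises(self, rng, tmp_path):
        cube = make_cube(rng, bands=8)
        path = tmp_path / "bad.hdr"
        write_envi(cube, path)
        text = path.read_text().replace(
            "bands = 8", "bands = 8").splitlines()
        # drop one wavelength from the header list
        out = []
        for line in text:
            if line.startswith("wavelength"):
                vals = line.split("{")[1].strip(" }").split(",")[:-1]
                line = "wavelength = { " + ",".join(vals) + " }"
            out.append(line)
        path.write_text("\n".join(out) + "\n")
        with pytest.raises(BandMismatchError):
            read_envi(path)

    def test_binary_size_mismatch_raises(self, rng, tmp_path):
        cube = make_cube(rng)
        path = tmp_path / "short.hdr"
        write_envi(cube, path, dtype=np.float32)
        binary = tmp_path / "short.raw"
        binary.write_bytes(binary.read_bytes()[:-40])
        with pytest.raises(BandMismatchError):
            read_envi(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_envi(tmp_path / "nope.hdr")

    def test_unsupported_interleave_raises(self, rng, tmp_path):
        cube = make_cube(rng)
        path = tmp_path / "c.hdr"
        write_envi(cube, path)
        path.write_text(path.read_text().replace("interleave = bil",
                                                 "interleave = weird"))
        with pytest.raises(UnsupportedInterleaveError):
            read_envi(path)


class TestCalibration:
    def _refs(self, bands):
        wl = np.arange(bands, dtype=float)
        return ReferenceFrames(dark=100 + wl, white=3000 + 5 * wl)

    def test_sample_equals_white_gives_one(self):
        refs = self._refs(6)
        raw = Hypercube(np.broadcast_to(refs.white, (4, 4, 6)).copy(),
                        np.arange(6.0), "raw")
        out = calibrate_reflectance(raw, refs)
        assert np.allclose(out.data, 1.0)
        assert out.kind == "reflectance"

    def test_sample_equals_dark_gives_zero(self):
        refs = self._refs(6)
        raw = Hypercube(np.broadcast_to(refs.dark, (4, 4, 6)).copy(),
                        np.arange(6.0), "raw")
        assert np.allclose(calibrate_reflectance(raw, refs).data, 0.0)

    def test_midpoint_gives_half(self):
        refs = self._refs(6)
        raw = Hypercube(np.broadcast_to((refs.dark + refs.white) / 2,
                                        (4, 4, 6)).copy(),
                        np.arange(6.0), "raw")
        assert np.allclose(calibrate_reflectance(raw, refs).data, 0.5)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(7)
        refs = self._refs(5)
        raw = Hypercube(rng.uniform(200, 2500, (3, 3, 5)), np.arange(5.0), "raw")
        base = calibrate_reflectance(raw, refs).data
        scaled = calibrate_reflectance(
            Hypercube(raw.data * scale, raw.wavelengths, "raw"),
            ReferenceFrames(refs.dark * scale, refs.white * scale)).data
        assert np.allclose(scaled, base, atol=1e-10)

    def test_white_not_above_dark_names_band(self):
        refs = ReferenceFrames(dark=np.array([100.0, 100, 100]),
                               white=np.array([3000.0, 90, 3000]))
        raw = Hypercube(np.full((2, 2, 3), 500.0), np.arange(3.0), "raw")
        with pytest.raises(CalibrationError, match="1"):
            calibrate_reflectance(raw, refs)

    def test_band_count_mismatch(self, rng):
        raw = make_cube(rng, bands=10)
        with pytest.raises(BandMismatchError):
            calibrate_reflectance(raw, self._refs(8))

    def test_clip_ceiling(self):
        refs = self._refs(3)
        raw = Hypercube(np.full((2, 2, 3), 1e6), np.arange(3.0), "raw")
        assert calibrate_reflectance(raw, refs).data.max() == pytest.approx(1.5)


class TestBands:
    def test_exclude_256_to_240(self, rng):
        cube = make_cube(rng, bands=256)
        out = exclude_bands(cube, 16)
        assert out.n_bands == 240
        assert out.wavelengths.size == 240
        assert np.array_equal(out.wavelengths, cube.wavelengths[16:])
        assert np.array_equal(out.data, cube.data[:, :, 16:])

    def test_exclude_zero_is_identity(self, rng):
        cube = make_cube(rng)
        assert exclude_bands(cube, 0) is cube

    def test_exclude_too_many_raises(self, rng):
        with pytest.raises(ValueError):
            exclude_bands(make_cube(rng, bands=10), 10)


class TestAbsorbance:
    @pytest.mark.parametrize("r, expected", [(1.0, 0.0), (0.01, 2.0),
                                             (0.5, np.log10(2.0))])
    def test_closed_form(self, r, expected):
        cube = Hypercube(np.full((2, 2, 3), r), np.arange(3.0), "reflectance")
        assert np.allclose(to_absorbance(cube).data, expected)

    def test_floor_prevents_infinity(self):
        cube = Hypercube(np.zeros((2, 2, 3)), np.arange(3.0), "reflectance")
        out = to_absorbance(cube)
        assert np.isfinite(out.data).all()
        assert np.allclose(out.data, 4.0)  # -log10(1e-4)

    def test_wrong_kind_raises(self, rng):
        with pytest.raises(ValueError):
            to_absorbance(make_cube(rng, kind="raw"))

    def test_array_input(self):
        assert to_absorbance(np.array([0.5])) == pytest.approx(np.log10(2))
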