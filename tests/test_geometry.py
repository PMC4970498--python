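import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sfxprep import BeamGeometry, assemble, parse_geometry, q_of, resolution_of
from sfxprep.geometry import (
    GeometryError,
    GeometryParseError,
    GeometryPanel,
    build_geometry_map,
    pixel_radius_map,
)
from sfxprep.synthetic import simple_geometry_text


def _panel_text(name, min_fs, max_fs, min_ss, max_ss, corner_x, corner_y,
                fs="+1.0x", ss="+1.0y", res=10000.0):
    return "".join(
        f"{name}/{k} = {v}\n" for k, v in [
            ("min_fs", min_fs), ("max_fs", max_fs),
            ("min_ss", min_ss), ("max_ss", max_ss),
            ("corner_x", corner_x), ("corner_y", corner_y),
            ("fs", fs), ("ss", ss), ("res", res),
        ]
    )


class TestParse:
    def test_identity_panel_maps_lab_coords_to_raw_indices(self):
        geom = parse_geometry(_panel_text("p0", 0, 63, 0, 63, 0.0, 0.0))
        assert geom.raw_shape == (64, 64)
        px = 1e-4
        assert geom.x_map[0, 0] == pytest.approx(0.0)
        assert geom.x_map[5, 7] == pytest.approx(7 * px)
        assert geom.y_map[5, 7] == pytest.approx(5 * px)

    def test_two_panels_with_gap_leave_unmapped_columns(self):
        text = (_panel_text("p0", 0, 63, 0, 63, 0.0, 0.0)
                + _panel_text("p1", 64, 127, 0, 63, 70.0, 0.0))
        geom = parse_geometry(text)
        assert geom.lab_shape[1] >= 134
        frame = np.ones(geom.raw_shape)
        img = assemble(frame, geom, fill=np.nan)
        assert np.isnan(img[:, 64:70]).all()
        assert np.isfinite(img[:, :64]).all()
        assert np.isfinite(img[:, 70:134]).all()

    def test_missing_corner_x_is_a_parse_error_naming_the_panel(self):
        text = _panel_text("p0", 0, 7, 0, 7, 0.0, 0.0)
        text = "\n".join(l for l in text.splitlines() if "corner_x" not in l)
        with pytest.raises(GeometryParseError, match="p0"):
            parse_geometry(text)

    def test_overlapping_slabs_rejected(self):
        text = (_panel_text("p0", 0, 7, 0, 7, 0.0, 0.0)
                + _panel_text("p1", 4, 11, 0, 7, 20.0, 0.0))
        with pytest.raises(GeometryError, match="overlap"):
            parse_geometry(text)

    def test_unknown_keys_ignored_and_defaults_inherited(self, caplog):
        text = ("res = 5000\nclen = 0.12\n"
                + "\n".join(l for l in _panel_text("p0", 0, 7, 0, 7, 0.0, 0.0).splitlines()
                            if "res" not in l) + "\n")
        geom = parse_geometry(text)
        assert geom.panels[0].pixel_size == pytest.approx(1 / 5000)

    def test_degenerate_axis_vectors_rejected(self):
        with pytest.raises(GeometryError, match="degenerate"):
            GeometryPanel("p", 0, 7, 0, 7, fs_vec=(1.0, 0.0), ss_vec=(2.0, 0.0),
                          corner_x=0, corner_y=0, pixel_size=1e-4)


class TestAssemble:
    def test_identity_geometry_is_identity_on_images(self, rng):
        geom = parse_geometry(_panel_text("p0", 0, 31, 0, 31, 0.0, 0.0))
        frame = rng.normal(size=(32, 32))
        assert np.array_equal(assemble(frame, geom), frame)

    def test_constant_frame_fills_every_mapped_cell(self):
        text = (_panel_text("p0", 0, 15, 0, 15, 0.0, 0.0)
                + _panel_text("p1", 16, 31, 0, 15, 20.0, 0.0))
        geom = parse_geometry(text)
        img = assemble(np.full(geom.raw_shape, 7.5), geom)
        assert np.all(img[np.isfinite(img)] == 7.5)

    def test_rotated_panel_matches_per_pixel_placement_oracle(self, rng):
        # second panel rotated 90 deg: fs along +y, ss along -x
        text = (_panel_text("p0", 0, 15, 0, 15, 0.0, 0.0)
                + _panel_text("p1", 16, 31, 0, 15, 40.0, 0.0,
                              fs="+1.0y", ss="-1.0x"))
        geom = parse_geometry(text)
        frame = rng.normal(size=geom.raw_shape)
        img = assemble(frame, geom, fill=np.nan)

        # oracle: place each raw pixel individually from the panel arithmetic
        expected = np.full(geom.lab_shape, np.nan)
        panels = {p.name: p for p in geom.panels}
        xs, ys = [], []
        coords = {}
        for p in panels.values():
            for ss in range(p.min_ss, p.max_ss + 1):
                for fs in range(p.min_fs, p.max_fs + 1):
                    i_fs, i_ss = fs - p.min_fs, ss - p.min_ss
                    x = p.corner_x + i_fs * p.fs_vec[0] + i_ss * p.ss_vec[0]
                    y = p.corner_y + i_fs * p.fs_vec[1] + i_ss * p.ss_vec[1]
                    coords[(ss, fs)] = (x, y)
                    xs.append(x)
                    ys.append(y)
        x0, y0 = min(xs), min(ys)
        for (ss, fs), (x, y) in coords.items():
            expected[round(y - y0), round(x - x0)] = frame[ss, fs]
        np.testing.assert_array_equal(np.isnan(img), np.isnan(expected))
        np.testing.assert_allclose(img[np.isfinite(img)], expected[np.isfinite(expected)])

    def test_pixel_conservation(self, rng):
        text = (_panel_text("p0", 0, 15, 0, 15, 0.0, 0.0)
                + _panel_text("p1", 16, 31, 0, 15, 18.0, 3.0))
        geom = parse_geometry(text)
        frame = rng.normal(size=geom.raw_shape)
        img = assemble(frame, geom, fill=np.nan)
        assert np.isfinite(img).sum() == geom.covered.sum()
        assert np.nansum(img) == pytest.approx(frame[geom.covered].sum())

    def test_shape_mismatch_raises(self):
        geom = parse_geometry(_panel_text("p0", 0, 7, 0, 7, 0.0, 0.0))
        with pytest.raises(ValueError, match="shape"):
            assemble(np.zeros((4, 4)), geom)


class TestScattering:
    def test_q_closed_form_at_45_degrees(self):
        beam = BeamGeometry(wavelength=1.0, detector_distance=0.1)
        expected = 4 * math.pi * math.sin(math.radians(22.5))
        assert q_of(0.1, beam) == pytest.approx(expected, abs=1e-6)

    def test_small_angle_limit(self):
        beam = BeamGeometry(wavelength=1.0, detector_distance=1.0)
        q = q_of(0.001, beam)
        assert q == pytest.approx(2 * math.pi * 0.001 / 1.0, rel=1e-4)

    def test_q_zero_at_beam_axis_and_monotone(self):
        beam = BeamGeometry(wavelength=1.5, detector_distance=0.2)
        assert q_of(0.0, beam) == 0.0
        radii = np.linspace(0, 0.5, 100)
        assert np.all(np.diff(q_of(radii, beam)) > 0)

    def test_resolution_closed_form_and_monotone_decrease(self):
        beam = BeamGeometry(wavelength=1.0, detector_distance=0.1)
        assert resolution_of(0.1, beam) == pytest.approx(1.30656, abs=1e-4)
        assert resolution_of(0.2, beam) < resolution_of(0.1, beam)

    def test_zero_radius_resolution_is_infinite(self):
        beam = BeamGeometry(wavelength=1.0, detector_distance=0.1)
        assert resolution_of(0.0, beam) == math.inf

    @given(st.floats(min_value=1e-6, max_value=10.0),
           st.floats(min_value=0.1, max_value=3.0),
           st.floats(min_value=0.01, max_value=2.0))
    def test_q_times_dspacing_is_two_pi(self, r, wavelength, distance):
        beam = BeamGeometry(wavelength=wavelength, detector_distance=distance)
        assert q_of(r, beam) * resolution_of(r, beam) == pytest.approx(2 * math.pi, rel=1e-10)

    def test_invalid_beam_parameters_rejected(self):
        with pytest.raises(ValueError):
            BeamGeometry(wavelength=0.0, detector_distance=0.1)
        with pytest.raises(ValueError):
            BeamGeometry(wavelength=1.0, detector_distance=-1.0)


def test_random_toy_geometries_match_brute_force_placement(rng):
    """Assembly equals direct per-pixel placement on random multi-panel layouts."""
    rotations = [((1, 0), (0, 1)), ((0, 1), (-1, 0)), ((-1, 0), (0, -1)), ((0, -1), (1, 0))]
    for trial in range(10):
        n_panels = int(rng.integers(1, 5))
        panels = []
        offset_fs = 0
        for i in range(n_panels):
            w, hgt = int(rng.integers(4, 33)), int(rng.integers(4, 33))
            fs_vec, ss_vec = rotations[int(rng.integers(0, 4))]
            panels.append(GeometryPanel(
                name=f"p{i}",
                min_fs=offset_fs, max_fs=offset_fs + w - 1,
                min_ss=0, max_ss=hgt - 1,
                fs_vec=fs_vec, ss_vec=ss_vec,
                corner_x=float(i * 80), corner_y=float(rng.integers(-10, 10)),
                pixel_size=1e-4,
            ))
            offset_fs += w
        geom = build_geometry_map(panels)
        frame = rng.normal(size=geom.raw_shape)
        img = assemble(frame, geom, fill=np.nan)

        placed = {}
        for p in panels:
            for ss in range(p.min_ss, p.max_ss + 1):
                for fs in range(p.min_fs, p.max_fs + 1):
                    x = p.corner_x + (fs - p.min_fs) * p.fs_vec[0] + (ss - p.min_ss) * p.ss_vec[0]
                    y = p.corner_y + (fs - p.min_fs) * p.fs_vec[1] + (ss - p.min_ss) * p.ss_vec[1]
                    placed[(ss, fs)] = (x, y)
        xs = [x for x, _ in placed.values()]
        ys = [y for _, y in placed.values()]
        expected = np.full(img.shape, np.nan)
        for (ss, fs), (x, y) in placed.items():
            expected[round(y - min(ys)), round(x - min(xs))] = frame[ss, fs]
        np.testing.assert_allclose(img, expected, equal_nan=True)


def test_radius_map_matches_hand_computation():
    text = simple_geometry_text((8, 8), pixel_size=2e-4, center=(3.0, 3.0))
    geom = parse_geometry(text)
    r = pixel_radius_map(geom)
    assert r[3, 3] == pytest.approx(0.0)
    assert r[3, 7] == pytest.approx(4 * 2e-4)
    assert r[0, 0] == pytest.approx(math.hypot(3, 3) * 2e-4)
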