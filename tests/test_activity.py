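"""Patchy activity: propagator values, tuning curve, source selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odcolumn import (
    GridSpec,
    PropagatorParams,
    Stimulus,
    TuningParams,
    build_activity,
    build_map,
    locate_source,
    op_tuning_weight,
    propagator,
)
from odcolumn.cortexmap import LEFT
from odcolumn.errors import ConfigurationError, InvalidParameterError


@pytest.fixture(scope="module")
def grid8():
    return GridSpec.from_extent(8.0, 8.0, h=0.125, duration=8.0, dt=0.1)


class TestPropagator:
    def test_value_at_source(self, grid8):
        src = (0.0625, 0.0625)  # a grid sample
        G = propagator(src, 0.0, PropagatorParams(), grid8)
        i, j = grid8.nearest_index(*src)
        assert G[i, j] == pytest.approx(2.25)
        assert G.max() == pytest.approx(2.25)

    def test_value_one_period_along_axis(self, grid8):
        # exp(-a^2/(2 dx^2)) * 1.5 * 1.5 at distance a = 2 mm, delta_x = 2.83
        src = (0.0625, 0.0625)
        G = propagator(src, 0.0, PropagatorParams(), grid8)
        i, j = grid8.nearest_index(src[0] + 2.0, src[1])
        expected = np.exp(-4.0 / (2 * 2.83**2)) * 2.25
        assert G[i, j] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(1.7528, abs=1e-3)

    def test_value_half_period(self, grid8):
        # envelope 0.9394 x lattice 0.5 x 1.5 = 0.7046
        src = (0.0625, 0.0625)
        G = propagator(src, 0.0, PropagatorParams(), grid8)
        i, j = grid8.nearest_index(src[0] + 1.0, src[1])
        assert G[i, j] == pytest.approx(0.70456, abs=1e-4)

    @pytest.mark.parametrize("angle_deg", [0.0, 30.0, 45.0, 120.0])
    def test_envelope_long_axis_follows_op(self, grid8, angle_deg):
        """Second-moment principal axis of the pattern tracks the bar OP."""
        G = propagator((0.0625, 0.0625), np.deg2rad(angle_deg),
                       PropagatorParams(), grid8)
        x = grid8.x[:, None] - 0.0625
        y = grid8.y[None, :] - 0.0625
        w = G / G.sum()
        cxx = np.sum(w * x * x)
        cyy = np.sum(w * y * y)
        cxy = np.sum(w * x * y)
        axis = 0.5 * np.arctan2(2 * cxy, cxx - cyy)
        diff = np.mod(axis - np.deg2rad(angle_deg) + np.pi / 2, np.pi) - np.pi / 2
        assert abs(np.rad2deg(diff)) < 5.0

    def test_invalid_widths(self):
        with pytest.raises(InvalidParameterError):
            PropagatorParams(delta_x=0.5, delta_y=1.0)


class TestTuning:
    def test_normalization_and_half_maximum(self):
        p = TuningParams(fwhm=40.0)
        assert op_tuning_weight(0.0, p) == pytest.approx(1.0)
        assert op_tuning_weight(np.deg2rad(20.0), p) == pytest.approx(0.5)
        assert op_tuning_weight(np.deg2rad(-20.0), p) == pytest.approx(0.5)

    def test_half_turn_symmetry(self):
        p = TuningParams()
        assert op_tuning_weight(np.pi / 2, p) == pytest.approx(
            op_tuning_weight(-np.pi / 2, p)
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-10, 10))
    def test_periodic_and_bounded(self, delta):
        p = TuningParams()
        w = op_tuning_weight(delta, p)
        assert 0 < w <= 1
        assert w == pytest.approx(op_tuning_weight(delta + np.pi, p), abs=1e-9)

    def test_invalid_fwhm(self):
        with pytest.raises(InvalidParameterError):
            TuningParams(fwhm=200.0)


@pytest.fixture(scope="module")
def fmap():
    return build_map(h=0.125, blocks=3)


class TestLocateSource:

    def test_source_matches_stimulus(self, fmap):
        sx, sy = locate_source(fmap, Stimulus(op_angle=0.0, eye="L"))
        i = np.argmin(np.abs(fmap.x - sx))
        j = np.argmin(np.abs(fmap.y - sy))
        assert fmap.od[i, j] == LEFT
        mis = np.mod(fmap.op[i, j] + np.pi / 2, np.pi) - np.pi / 2
        assert abs(np.rad2deg(mis)) < 2.0

    def test_source_near_od_boundary(self, fmap):
        sx, _ = locate_source(fmap, Stimulus(op_angle=0.0))
        dist = abs(np.mod(sx + 0.5, 1.0) - 0.5)
        assert dist < 0.25

    def test_rotated_bar_moves_source(self, fmap):
        s0 = locate_source(fmap, Stimulus(op_angle=0.0))
        s45 = locate_source(fmap, Stimulus(op_angle=np.deg2rad(45)))
        assert s0 != s45

    def test_deterministic(self, fmap):
        stim = Stimulus(op_angle=np.deg2rad(45))
        assert locate_source(fmap, stim) == locate_source(fmap, stim)

    def test_impossible_tolerance(self, fmap):
        with pytest.raises(ConfigurationError):
            locate_source(fmap, Stimulus(op_angle=0.3), tolerance_deg=1e-6)


class TestBuildActivity:
    def test_step_protocol(self, tiny_activity, tiny_grid):
        pre = tiny_activity.values[:, :, tiny_grid.time_index(0.5)]
        on = tiny_activity.values[:, :, tiny_grid.time_index(2.0)]
        post = tiny_activity.values[:, :, tiny_grid.time_index(6.0)]
        assert np.all(pre == 0) and np.all(post == 0)
        assert on.max() == pytest.approx(1.0)

    def test_non_negative_and_gated(self, tiny_activity, tiny_map, tiny_stim):
        assert tiny_activity.values.min() >= 0
        other_eye = tiny_map.od != tiny_stim.eye_code
        assert np.all(tiny_activity.pattern[other_eye] == 0)

    def test_patch_spacing_cardinal_and_diagonal(self):
        """Adjacent patches sit ~a apart at 0 deg and ~sqrt(2) a at 45 deg."""
        from odcolumn import metrics

        fmap = build_map(h=0.125, blocks=3)
        grid = GridSpec.from_extent(12.0, 12.0, h=0.125, duration=8.0, dt=0.1)
        for deg, expected in [(0.0, 2.0), (45.0, 2.0 * np.sqrt(2))]:
            stim = Stimulus(op_angle=np.deg2rad(deg), onset=1.0, offset=4.0)
            phi = build_activity(fmap, stim, grid)
            prof = metrics.extract_profile(phi.pattern, grid, stim.op_angle)
            res = metrics.modulation(prof)
            peak_at = prof.distances[
                np.argmin(np.abs(prof.values - res.p_minus))
            ]
            assert abs(abs(peak_at) - expected) < 0.35

    def test_offset_beyond_duration(self, tiny_map, tiny_grid):
        with pytest.raises(InvalidParameterError):
            build_activity(tiny_map, Stimulus(onset=1.0, offset=9.0), tiny_grid)

    def test_stimulus_validation(self):
        with pytest.raises(InvalidParameterError):
            Stimulus(eye="X")
        with pytest.raises(InvalidParameterError):
            Stimulus(onset=5.0, offset=2.0)
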