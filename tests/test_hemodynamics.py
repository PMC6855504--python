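"""Transfer function and BOLD forward model."""

import numpy as np
import pytest

from odcolumn import (
    GridSpec,
    HemodynamicParams,
    point_hrf,
    predict_bold,
    transfer_function,
)
from odcolumn.activity import NeuralField
from odcolumn.errors import GridMismatchError, InvalidParameterError
from odcolumn.hemodynamics import temporal_kernel


def _impulse_field(grid, i=None, j=None):
    values = np.zeros(grid.shape())
    if i is None:
        i, j = grid.nearest_index(0.0, 0.0)
    values[i, j, 0] = 1.0
    return NeuralField(grid=grid, values=values, pattern=values[:, :, 0],
                       timecourse=values[i, j], source=(grid.x[i], grid.y[j]))


def _spatial_fwhm(field2d, grid):
    """FWHM of an isotropic peak via the x-cut through its maximum."""
    i, j = np.unravel_index(np.argmax(field2d), field2d.shape)
    cut = field2d[:, j]
    half = cut[i] / 2
    above = np.flatnonzero(cut >= half)
    return (above[-1] - above[0] + 1) * grid.h


class TestTransferFunction:
    def test_conjugate_symmetry(self, tiny_transfer):
        H = tiny_transfer.values
        flipped = H[
            np.ix_(*((-np.arange(n)) % n for n in H.shape))
        ]
        np.testing.assert_allclose(flipped, np.conj(H), rtol=0, atol=1e-12)

    def test_k0_slice_is_peak_then_undershoot(self, proto_transfer, proto_grid):
        hrf = np.fft.ifft(proto_transfer.values[0, 0, :]).real
        imax, imin = np.argmax(hrf), np.argmin(hrf)
        assert hrf[imax] > 0 > hrf[imin]
        assert imax < imin  # undershoot follows the main peak
        assert proto_grid.t[imax] < 10.0

    def test_kernel_modes(self, tiny_grid):
        b = temporal_kernel(HemodynamicParams(), tiny_grid.t)
        t_peak = tiny_grid.t[np.argmax(b)]
        assert t_peak == pytest.approx(5.5, abs=0.1)

    def test_gamma_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            HemodynamicParams(gamma=0.0)

    def test_default_kappa_is_gamma_over_nu(self):
        p = HemodynamicParams(gamma=1.6, nu_beta=0.5)
        assert p.kappa_eff == pytest.approx(3.2)
        assert HemodynamicParams(kappa=1.0).kappa_eff == 1.0

    def test_finite_everywhere(self, tiny_transfer):
        assert np.all(np.isfinite(tiny_transfer.values))


class TestPredictBold:
    def test_zero_maps_to_zero(self, tiny_grid, tiny_transfer, tiny_activity):
        zero = NeuralField(
            grid=tiny_grid, values=np.zeros(tiny_grid.shape()),
            pattern=np.zeros(tiny_grid.spatial_shape()),
            timecourse=np.zeros(tiny_grid.nt), source=(0.0, 0.0),
        )
        assert np.all(predict_bold(zero, tiny_transfer).values == 0)

    def test_exact_linearity(self, tiny_activity, tiny_transfer, tiny_grid):
        y1 = predict_bold(tiny_activity, tiny_transfer).values
        doubled = NeuralField(
            grid=tiny_grid, values=2 * tiny_activity.values,
            pattern=tiny_activity.pattern, timecourse=tiny_activity.timecourse,
            source=tiny_activity.source,
        )
        y2 = predict_bold(doubled, tiny_transfer).values
        np.testing.assert_allclose(y2, 2 * y1, rtol=0, atol=1e-14)

    def test_shift_equivariance(self, tiny_activity, tiny_transfer, tiny_grid):
        shift = int(round(4.0 / tiny_grid.h))  # one map period
        rolled = NeuralField(
            grid=tiny_grid, values=np.roll(tiny_activity.values, shift, axis=0),
            pattern=np.roll(tiny_activity.pattern, shift, axis=0),
            timecourse=tiny_activity.timecourse, source=tiny_activity.source,
        )
        y_roll = predict_bold(rolled, tiny_transfer).values
        y = predict_bold(tiny_activity, tiny_transfer).values
        np.testing.assert_allclose(y_roll, np.roll(y, shift, axis=0), atol=1e-12)

    def test_energy_bound(self, tiny_activity, tiny_transfer):
        y = predict_bold(tiny_activity, tiny_transfer).values
        bound = np.abs(tiny_transfer.values).max() * np.linalg.norm(
            tiny_activity.values
        )
        assert np.linalg.norm(y) <= bound * (1 + 1e-12)

    def test_grid_mismatch(self, tiny_activity):
        other = GridSpec.from_extent(4.0, 4.0, h=0.125, duration=4.0, dt=0.1)
        H = transfer_function(HemodynamicParams(), other)
        with pytest.raises(GridMismatchError):
            predict_bold(tiny_activity, H)

    def test_stimulus_time_course_shape(self, proto_bold, proto_grid):
        """Rise after onset, peak, then a post-stimulus undershoot."""
        phi, bold = proto_bold
        i, j = proto_grid.nearest_index(*phi.source)
        ts = bold.values[i, j, :]
        i_on = proto_grid.time_index(3.0)
        assert abs(ts[:i_on]).max() < 0.25 * ts.max()  # near-quiet baseline
        assert ts.max() > 0
        i_peak = np.argmax(ts)
        assert proto_grid.t[i_peak] > 3.0
        assert ts[i_peak:].min() < 0  # post-stimulus undershoot


class TestPointHrf:
    def test_isotropy(self, tiny_grid):
        _, snap = point_hrf(HemodynamicParams(), tiny_grid)
        frame = snap[:, :, tiny_grid.time_index(3.0)]
        i, j = tiny_grid.nearest_index(0.0, 0.0)
        # x- and y-cuts through the impulse agree (H depends on |k| only)
        np.testing.assert_allclose(frame[:, j], frame[i, :], atol=1e-10)

    def test_speed_widens_spread(self, tiny_grid):
        fwhms = []
        for nu in (1.0, 2.0):
            ts, snap = point_hrf(HemodynamicParams(nu_beta=nu), tiny_grid)
            frame = snap[:, :, np.argmax(ts)]
            fwhms.append(_spatial_fwhm(frame, tiny_grid))
        assert fwhms[1] > fwhms[0]

    def test_damping_shrinks_spread(self, tiny_grid):
        fwhms = []
        for gamma in (0.8, 1.6):
            ts, snap = point_hrf(HemodynamicParams(gamma=gamma), tiny_grid)
            frame = snap[:, :, np.argmax(ts)]
            fwhms.append(_spatial_fwhm(frame, tiny_grid))
        assert fwhms[1] < fwhms[0]

    def test_space_integral_tracks_k0_mode(self, tiny_grid, tiny_transfer):
        # Parseval/zero-mode identity: the spatial sum of the impulse
        # response equals the inverse transform of the k = 0 slice of H.
        _, snap = point_hrf(HemodynamicParams(), tiny_grid)
        integral = snap.sum(axis=(0, 1))
        k0 = np.fft.ifft(tiny_transfer.values[0, 0, :]).real
        np.testing.assert_allclose(integral, k0, atol=1e-10)
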