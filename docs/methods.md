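# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `odcolumn`, and what the simulations do and do not show.

## Cortical feature map

The map idealizes V1's joint ocular-dominance / orientation-preference
architecture. A hypercolumn is a square of width a = 2 mm containing one
1 mm left-eye and one 1 mm right-eye stripe (vertical boundaries at
multiples of a/2, with x = 0 on a boundary). Orientation preference is a
pinwheel field: in the first-quadrant cell,
`phi(x, y) = 1/2 [atan2(y - a/2, x - a/2) + pi]` (mod pi), and the other
three quadrants of the fundamental 2a x 2a block follow by reflection
across the axes with `phi -> pi - phi`, so adjacent pinwheels have
opposite handedness. The block tiles periodically; the standard patch is
3 x 3 blocks = 12 x 12 mm = 36 hypercolumns. Conventions: cell-centered
samples, origin at the patch center, arrays indexed (x, y) row-major,
lengths in mm; the OP value at the singular pinwheel center is defined
as 0.

Two geometric facts worth knowing. First, around a pinwheel at the
center of a square cell the angular area density is not uniform — it
varies with the squared corner distance, so OP histogram bins differ by
up to a factor of two even though every orientation is represented.
Second, translating the map by one hypercolumn (a, 0) or by (a, a)
rotates the local OP by 90 degrees; like-for-like OP repeats only at the
2a block period. This matters for how activity is composed (below).

## Patchy neural activity

A short oriented bar presented to one eye excites neurons preferring
that orientation; the excitation spreads through long-range patchy
horizontal connections to like-feature patches in neighbouring
visual-field representations. The spatial pattern is

    G(r, r') = exp[-(x_g^2 / 2 dx^2 + y_g^2 / 2 dy^2)]
               x (cos(kx (x - x'))/2 + 1)(cos(ky (y - y'))/2 + 1),

with (x_g, y_g) the offsets rotated by the bar orientation, envelope
widths dx = 2.83 mm and dy = 1 mm (a 3:1 aspect ratio, long axis along
the OP), and lattice frequencies kx = ky = 2 pi / a. The lattice's
half-depth cosine gives peaks of ~1.3 mm full width, which is what a
40-degree-FWHM orientation tuning curve translates to on this map — the
peak width is the spatial expression of the tuning width.

The source location is the sample in the central block whose stored OP
best matches the bar (ties broken toward the nearest OD boundary, then
lexicographically); this lands next to a left/right boundary, matching
the intended stimulus placement. The pattern is multiplied by a hard
monocular gate (zero in the unstimulated eye's stripes; leakage is a
parameter, default 0) and normalized to a spatial maximum of 1; the time
course is a unit step from 3 to 10 s of the 23 s protocol.

No additional orientation-tuning mask over the map is applied by
default: because a one-hypercolumn translation rotates OP by 90 degrees,
masking by map OP would suppress exactly the nearest lattice patches and
double the apparent patch spacing, destroying the string-of-pearls
structure the propagator is meant to produce (the option exists as
`tuning_mask=True` on `build_activity` for comparison). With the default
composition, adjacent patches lie ~a apart for cardinal stimuli and
~sqrt(2) a apart for oblique ones — the oblique geometry is what makes
45/135-degree stimuli the most detectable, since wider-spaced patches
survive hemodynamic blurring better.

## Hemodynamic forward model

BOLD is modelled as linear, shift-invariant spatiotemporal filtering,
`Y(k, w) = H(k, w) phi(k, w)`, with

    H(k, w) = B(w) * nu^2 kappa^2 / (nu^2 (|k|^2 + kappa^2) - w^2 + 2 i Gamma w),

where Gamma is the hemodynamic wave damping rate (default 0.8 1/s) and
nu_beta the wave speed (default 2 mm/s). The regularization wavenumber
kappa defaults to its physical damped-wave value Gamma / nu_beta, for
which the denominator is `nu^2 |k|^2 + Gamma^2 - w^2 + 2 i Gamma w` with
poles at `w = +/- nu |k| + i Gamma` — damped travelling waves. The key
consequence is the low-frequency spatial attenuation
`Gamma^2 / (nu^2 |k|^2 + Gamma^2)`: at the columnar wavenumber
k = pi rad/mm it is 0.016 for default parameters, rising to 0.51 at
Gamma = 1.6, nu = 0.5 — which is why high damping and low speed make
columns detectable. A fixed kappa (e.g. 1 rad/mm) can be supplied
instead, but it weakens these dependences and roughly triples the
predicted BOLD modulation; the physical default is used throughout.

`B(w)` is the transform of a difference-of-gammas kernel (unit-scale
gamma densities with modes at 5.5 s and 11 s, undershoot ratio 0.2),
giving the canonical peak-then-undershoot time course. The sign of the
`i Gamma w` term is chosen so poles sit in the upper half plane, which
is the causal convention for numpy's inverse FFT (`e^{+i w t}`);
conjugate symmetry `H(-k, -w) = H*(k, w)` holds either way and the
unpaired temporal Nyquist bin is forced real so real fields map to real
fields exactly.

Boundaries are periodic (FFT-native) in space and time: the map is
periodic by construction and the response is short-range compared with
the patch. The undershoot has not fully decayed by the end of the 23 s
window (a few percent of peak wraps into the pre-onset baseline); this
is shared by any windowed treatment of this protocol and does not affect
the 9.7 s snapshot on which all measurements are taken.

The overall gain is not identifiable from the modulation statistics
(which are scale-invariant) and is calibrated once so the smoothed
default-parameter response at 0.25 mm peaks at ~0.2 at the 9.7 s
snapshot (`DEFAULT_GAIN = 5.1199`, frozen; `calibrate_gain` recomputes
it).

## Acquisition and noise

Scanner resolution dx is emulated by zeroing all spatial-frequency modes
with `|k| >= k_c = pi / dx` (an isotropic sharp window — sinc smoothing
in coordinate space), then sampling the smoothed field at the centers of
a dx voxel grid anchored at the patch corner (nearest native sample;
center sampling rather than voxel averaging, a second-order distinction
under the k_c prefilter). Measurement noise is a single spatial Gaussian
white field per acquisition — frozen in time, added to every frame —
passed through the same k-space filter as the signal and normalized so
its rms equals `signal_ref / (200 (dx / 1 mm)^2)`, the task-based SNR
calibration for dx x dx x 3 mm voxels; `signal_ref` is the spatial peak
of the noise-free smoothed response at the measurement snapshot. The
frozen (purely spatial) noise model is deliberate: temporally
independent noise is almost entirely averaged away by the spatiotemporal
Wiener filter and would make the noisy-case results trivially identical
to the noise-free ones.

## Wiener estimation

The Wiener spectrum is `D = H* / (|H|^2 + sigma_abs^2)`. The constant
`sigma` is a dimensionless noise-to-signal ratio, converted inside
`deconvolve`/`bold_wiener` to the data's amplitude scale via the
snapshot peak; this makes the estimation chain invariant to the forward
gain. The matched choice when noise was simulated is the inverse task
SNR, `1 / (200 dx^2)` (0.08 at 0.25 mm); noise-free demonstrations use
0.06. `H D Y` is the Wiener-denoised BOLD ("BOLD-Wiener"); the pipeline
estimates neural activity by deconvolving that signal (net spectrum
`H |H|^2 / (|H|^2 + sigma^2)^2` times `1/H`), which suppresses the ring
of marginal wavenumbers (|H| ~ sigma) whose noise a single inverse pass
amplifies most. Pixelated images are zero-order-hold upsampled to the
native grid before filtering.

## Modulation measurement

Profiles are sampled at native spacing over +/- 2a along the stimulus
orientation through the field's global maximum (bilinear interpolation,
periodic wrap), at t = 9.7 s for time-resolved fields. In the statistic
`xi = [(P+ + P-)/2 - M] / [(P+ + P-)/2 + M]`, P+ is the central maximum;
the adjacent maximum P- is the nearest prominent local peak (prominence
floor 0.5% of P+) lying at least a/2 = 1 mm from the center — genuine
patches cannot be closer than the lattice period, whereas band-limiting
(Gibbs) ringing lobes hug the central peak — and M is the minimum in
between, clamped at zero because the statistic applies to non-negative
signals whose band-limited representation can ring slightly below zero.
If no such peak/trough pair exists the modulation is 0. Deconvolved
activity estimates are quantified on their magnitude: the estimand is a
non-negative activity and the signed Wiener output's oscillations about
zero are filter artifacts. Noisy BOLD is measured on the BOLD-Wiener
signal; noise-free BOLD on the acquired (pixelated) image — pixelation
is what removes the apparent modulation at coarse voxels (e.g. a 2 mm
pattern sampled at 0.75 mm), as the k-space cutoff alone would pass the
columnar frequency up to dx = 1 mm.

## Default study conditions and problem sizes

12 x 12 mm patch (36 hypercolumns) at native h = 0.0625 mm — finer than
the finest analysed voxel size of 0.125 mm, so "at 0.125 mm" genuinely
band-limits the field; 23 s at dt = 0.1 s; stimulus on 3-10 s; snapshot
9.7 s; voxel sizes 0.125-1.0 mm; SNR 200 at 1 mm; seed-averaged
quantities use 20 noise realizations. A full sweep runs in minutes on
one CPU; unit tests use a single-block (4 mm, 8 s) miniature.

## Known limitations

- The transfer function is a two-parameter damped-wave surrogate for the
  full physiological model (neuroglial drive, CBF, CBV, pressure, dHb),
  whose multi-pole spectrum is not reproduced here. The predicted BOLD
  modulations are accordingly somewhat higher than the reference values
  (~10% vs ~6% for the cardinal stimulus at fine resolution), and since
  the noise calibration is tied to the signal peak, noise degrades our
  noisy-case statistics correspondingly less. Trends across Gamma,
  nu_beta, voxel size and stimulus orientation are reproduced.
- With a hard monocular gate the inter-patch minima of the activity are
  exactly zero, so the neural modulation of the cardinal pattern reads
  100% rather than ~97%; a few-percent cross-eye leakage would lower it
  but no principled value is available (the gate's leakage is exposed as
  a parameter).
- Straight vertical OD stripes, fixed hypercolumn size, no retinotopic
  eccentricity scaling, no through-depth (3D) hemodynamics, and a linear
  hemodynamic regime throughout.
- Synthetic noise is spatial, Gaussian and white below the acquisition
  cutoff; physiological noise spectra, drift and motion are not modelled,
  so passing tests bound detectability under idealized noise only.
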