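# odcolumn

Can functional MRI see ocular-dominance (OD) and orientation-preference
(OP) columns in human primary visual cortex? `odcolumn` is a simulation
toolkit for answering that question quantitatively. It generates an
idealized OD/OP feature map of V1, drives it with a short oriented-bar
stimulus shown to one eye, predicts the resulting BOLD response through a
spatiotemporal hemodynamic transfer function, degrades the image to a
chosen scanner resolution with calibrated measurement noise, and then
tries to undo the hemodynamic blur by Wiener deconvolution. Detectability
is scored with a peak-trough modulation statistic at every stage, so the
question "is the columnar pattern still visible?" has a number attached
at native resolution, in raw BOLD, after denoising, and after
deconvolution.

It is aimed at people designing high-resolution (0.125-1 mm) fMRI
experiments of columnar architecture and at modellers studying how
hemodynamic spreading limits effective spatial resolution.

## Model

- **Cortical map** — square hypercolumns of width a = 2 mm, each holding a
  1 mm left-eye and a 1 mm right-eye stripe; OP pinwheels
  `phi(x, y) = 1/2 [atan2(y - y0, x - x0) + pi]` with neighbours of
  opposite chirality obtained by reflection, tiled periodically
  (default patch: 12 x 12 mm, 36 hypercolumns).
- **Patchy activity** — long-range horizontal connections are modelled as
  an oriented elliptic Gaussian envelope (widths 2.83 x 1 mm, long axis
  along the bar's orientation) times a cosine lattice of period a,
  `G(r, r') = exp[-(x_g^2/2 dx^2 + y_g^2/2 dy^2)] (cos(k x)/2 + 1)(cos(k y)/2 + 1)`,
  gated to the stimulated eye's stripes and switched on as a unit step
  from 3 s to 10 s of a 23 s protocol.
- **Hemodynamics** — linear spatiotemporal filtering
  `Y(k, w) = H(k, w) phi(k, w)` with
  `H = B(w) * Gamma^2 / (nu^2 |k|^2 + Gamma^2 - w^2 - 2 i Gamma w)`:
  a damped hemodynamic wave (damping Gamma = 0.8 1/s, speed
  nu_beta = 2 mm/s) times a difference-of-gammas temporal kernel (peak
  5.5 s, undershoot 11 s). High damping and low speed mean less spatial
  blurring of the columns.
- **Acquisition** — k-space cutoff `|k| < k_c = pi / dx` (sinc smoothing),
  frozen spatial Gaussian white noise normalized to a task SNR of
  `200 (dx / 1 mm)^2` for dx x dx x 3 mm voxels, then voxel-center
  sampling.
- **Wiener estimation** — `D = H* / (|H|^2 + sigma^2)` with sigma a
  noise-to-signal ratio; `H D Y` is the denoised "BOLD-Wiener" signal and
  deconvolving it yields the neural-activity estimate.
- **Modulation statistic** — on a profile through the response peak along
  the bar's orientation, `xi = [(P+ + P-)/2 - M] / [(P+ + P-)/2 + M]`
  with P+ the central peak, P- the adjacent patch peak and M the trough
  between them (epsilon denotes the same statistic on neural activity).

## Worked example

```python
import numpy as np
from odcolumn import (build_map, GridSpec, Stimulus, build_activity,
                      HemodynamicParams, transfer_function, predict_bold,
                      acquire, AcquisitionParams, WienerParams,
                      bold_wiener, deconvolve, measure, kspace_lowpass)

fmap = build_map(h=0.0625)               # 12 x 12 mm, 36 hypercolumn cells
grid = GridSpec.from_extent(12.0, 12.0, h=0.0625)   # 23 s protocol
stim = Stimulus(op_angle=np.deg2rad(45))            # oblique bar, left eye

phi = build_activity(fmap, stim, grid)
pattern = kspace_lowpass(phi.pattern, 0.125, grid)
eps = measure(pattern, grid, stim.op_angle)

H = transfer_function(HemodynamicParams(), grid)    # Gamma=0.8, nu_beta=2
bold = predict_bold(phi, H)
vox = acquire(bold, AcquisitionParams(dx=0.25, seed=0))

wp = WienerParams(sigma=1 / (200 * 0.25**2))        # matched NSR = 0.08
bw = bold_wiener(vox, H, wp)
xi = measure(bw, grid, stim.op_angle, t=9.7)
est = deconvolve(bw, H, wp, signal_ref=vox.signal_ref)
eps_hat = measure(np.abs(est), grid, stim.op_angle, t=9.7)
```

This prints (via the obvious `print` statements):

```
source at (-1.03125, -0.03125) mm
neural modulation  epsilon = 100.0%
acquired 48x48 voxels, noise rms 0.0159 (SNR 12.5)
noisy BOLD-Wiener  xi      = 12.1%  (P+=0.204, P-=0.141, M=0.135)
deconvolved        epsilon = 98.3%
```

Read: the neural pattern is perfectly modulated (adjacent activity
patches separated by silent cortex), hemodynamic blurring plus noise
leave only a 12% modulation in the denoised BOLD image at 0.25 mm, and
model-based deconvolution recovers a near-fully modulated estimate of the
underlying activity — the core feasibility argument for deconvolution-
assisted columnar imaging.

A command-line interface wraps the same pipeline:

```sh
odcolumn simulate --op-deg 45 --out sim        # map + activity + BOLD (NIfTI)
odcolumn acquire --dx 0.5 --seed 1             # scanner-resolution image
odcolumn deconvolve --input sim_bold.nii.gz --sigma 0.06
odcolumn sweep --config sweep.yaml --out sweep.csv
```

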