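# Methods

## Scope

`sfdimc` models the full computational chain of diffuse and sub-diffuse
spatial frequency domain imaging (SFDI): measuring and fitting a scattering
phase function (SPF), building a white Monte Carlo (wMC) forward reflectance
model with that SPF, inverting measured reflectance pairs into optical
properties through lookup tables (LUTs), and quantifying the error this
chain commits when the assumed SPF does not match the sample. No instrument
is involved: synthetic generators produce every input, with ground truth
attached, so each stage can be closed against known answers.

## Phase functions

The two-term Henyey-Greenstein (ttHG) density over the deflection cosine is

    p(x) = (1/4pi) [ alpha K(gf, x) + (1 - alpha) K(gb, x) ],
    K(g, x) = (1 - g^2) / (1 + g^2 - 2 g x)^{3/2},

with forward fraction `alpha` in [0, 1], forward anisotropy `gf` in [0, 1),
backward anisotropy `gb` in (-1, 0], and overall anisotropy
`g1 = alpha gf + (1 - alpha) gb`. The zinc-oxide-like default is
`(alpha, gf, gb) = (0.855, 0.983, 0)`, i.e. a strongly forward lobe plus a
14.5% isotropic backscatter fraction, giving g1 = 0.84.

Monte Carlo sampling uses a numerically tabulated inverse CDF: the density
is integrated over solid angle on a cosine grid of step 1e-4 and the
flipped relation is interpolated onto the CDF ladder `1e-4 : 1e-4 : 1-1e-4`.
Within each grid cell the integral uses 5-point Gauss-Legendre quadrature:
the forward peak of a `g = 0.98` lobe varies severalfold across the final
cells, and the trapezoid rule there misplaces ~2% of the total probability
mass, which biases the sampled mean cosine by ~4e-3 — outside the 3-standard
-error sampling tolerance this module holds itself to. Sampling interpolates
linearly in the table; uniforms outside the tabulated ladder clamp to the
table ends. Against the closed-form stHG quantile the table agrees to
better than 1e-4 in the cosine.

## Goniometry reduction

Raw scans are detector angle vs. normalized intensity on the instrument
grid (10-degree steps, 0-60 and 120-170 degrees; the band around 90 degrees
is occluded). Reduction: divide by the aperture solid angle
(planar-disc approximation, `pi (d/2)^2 / D^2`; 8.2 mm at 128 mm = 3.2 msr)
and the clear-host transmission; subtract the identically normalized
clear-sample scan at non-zero angles (surface-scatter correction, floored
at zero and flagged); convert detector angles to in-sample scattering
angles with the Snell association `asin((n_det/n_sample) sin t)` per branch
(n_sample defaults to 1.556; at 60 degrees the compression exceeds 26
degrees).

Each lobe is fitted as `s * stHG(g)` by trust-region least squares with the
published weighting (section maximum over each measurement, applied to
squared residuals) and multistart in g; the mixing fraction is
`alpha = s_f / (s_f + s_b)`. Two refinements proved necessary for accurate
recovery and are the package's own choices:

* **Cross-lobe subtraction.** Each section contains the tail of the other
  lobe (at 30-35 degrees in-sample the isotropic backscatter floor is
  comparable to the forward lobe), which biases independent fits
  (`gf` low by ~0.02, `alpha` by ~0.12 at the ZnO parameters). Three rounds
  of subtracting the fitted opposite lobe before refitting make the
  noiseless roundtrip exact to optimizer tolerance.
* **The 0-degree point.** Over the refraction-compressed forward range the
  (g, s) pair is nearly degenerate; without the transmission peak a 2%
  measurement noise inflates sigma(alpha) to ~2.5%. The peak is included by
  default, which is appropriate when the unscattered beam is removed or
  negligible (as in the generator); `include_zero_angle=False` drops it.

With the default seed, 2% multiplicative noise, and the paired
positive/negative-angle repeats averaged, the fit recovers alpha to 0.1%
and the anisotropies to ~3e-4. The information content of the backward
section is intrinsically low (five near-flat points spanning 0.17 in the
cosine), so `gb` scatters by ~0.02 per unit of relative noise; tolerances
tighter than that at higher noise levels are not statistically meaningful.

## Photon transport

A continuous (non-voxelized) homogeneous medium fills `0 <= z <= L`
(half-space: L effectively infinite). Steps are exponential with rate
`mus`; deflection cosines come from the tabulated inverse CDF, azimuth is
uniform (sampled by Marsaglia rejection, no trigonometry); directions are
renormalized each scattering. Boundaries apply unpolarized Fresnel
coefficients with probabilistic reflection, including total internal
reflection; entry applies probabilistic specular reflection at normal
incidence. Absorption is continuous Beer-Lambert weight decay along the
path with the deposit tallied, so launched weight equals
top + bottom + absorbed + in-flight-at-cap to machine precision (1e-9
asserted). In absorbing media a photon whose weight falls below
`weight_cutoff` (default 1e-7) deposits its residual as absorbed — the
energy ledger stays exact and the induced reflectance bias is below the
cutoff itself. Time of flight accumulates continuously as pathlength times
n/c. The RNG is an inline xorshift128+ seeded by splitmix64, giving
bit-reproducible runs per seed.

Three sources: pencil beam (white-MC base run), uniform disc beam on a
finite slab with cyclic lateral boundaries (R/T/transflectance), and a
sinusoidally patterned source `0.5 (1 + cos(2 pi fx x + phase))` over two
periods with cyclic boundaries (direct SFDI simulation). The patterned
domain is `depth_factor` (default 5) penetration depths deep; the
penetration depth uses `1/sqrt(3 mua (mua + mus') + (2 pi fx)^2)` but with
the fx term dropped for the domain-depth rule when the medium absorbs:
the diffuse DC component penetrates deeper than the AC pattern, and sizing
the domain to the fx-dependent depth measurably truncates DC at low fx
(a ~1% bias at fx = 0.1, mus'/mua = 500 in our tests). Exit profiles are
binned at 25 bins per period and normalized to the mean illumination, so
that three-phase demodulation
(`AC = (sqrt(2)/3) sqrt(sum of squared pairwise differences)`, DC = mean)
recovers the reflectance pair directly. Bin-averaging a cosine attenuates
the AC amplitude by exactly sinc(pi/25) = 0.9934; comparisons against the
continuous forward model apply this factor.

## White Monte Carlo forward model

The base run is a pencil beam on a half-space with `mua = 1e-8 mm^-1`,
`mus' = 10 mm^-1`, n = 1.56 against air, and a 300 ns time cap. Escaping
photons are histogrammed over exit radius and time of flight on log-spaced
grids: 750 bin centers from 1e-5 to 150 mm and from 1e-7 to 300 ns, edges
at geometric midpoints, with out-of-range weight kept in a guard tally
excluded from transforms. The same resolution on linear axes would need
~2e5 radius and ~3e6 time bins; the log grid is smaller by a factor above
1e6 while still resolving the sub-diffuse structure (the ttHG backscatter
excess peaks ~25 um and ~250 fs from the source).

Reflectance at arbitrary properties: `beta = mus'/10` rescales both bin
coordinates by `1/beta`; absorption multiplies each time bin by
`exp(-mua (c/n) t_scaled)`; summing over time and dividing by the scaled
annulus areas gives R(rho); the order-zero Hankel transform
`Rd(fx) = sum w_i J0(2 pi fx rho_i)` (midpoint quadrature on the log
annuli — the per-annulus weight times the Bessel factor) gives the
spatial-frequency reflectance. Against the closed-form transform of an
exponential profile the quadrature is accurate to 0.5%; the scaling law is
verified against independent transport runs at `beta` = 0.5 and 2 to
within Monte Carlo error.

Validation against the direct patterned-source simulation (10 frequencies
from 0.1 to 1.0 mm^-1, scattering-to-absorption ratios 500 and 5, at
mus' = 5 mm^-1) agrees within 3 combined standard errors at the desk-scale
photon budgets used in the tests (1.5e5-photon records, 2e4 photons per
phase).

**Problem sizes.** The test and acceptance records use reduced photon
counts and time caps chosen by convergence, not by the full-scale run:
Rd(fx = 1.0 mm^-1) evaluated at mus' = 5, mua = 0.01 changes by under 0.1%
when the record's time cap grows from 0.3 ns to 3 ns (absorption and
J0 oscillation kill the late tail), so the million-photon stHG comparison
records use a 0.5 ns cap, and the fixture records (1.5e5 photons) use 3 ns,
which also converges every DC evaluation in the suite to well below its
Monte Carlo error. Record uncertainty is estimated per bin from the
binned counts (unit-weight photons), and every stochastic assertion uses
3 combined standard errors.

## Lookup tables and inversion

The forward surface is computed on a dense log grid (mua 1e-4-10 mm^-1,
mus' 0.1-10 mm^-1, 120 points each by default), triangulated in
log-reflectance space, and interpolated onto fixed log-spaced reflectance
grids (DC 0.001-0.9 over 190 points, AC 0.001-0.7 over 170). Nodes outside
the attainable surface, nodes with AC >= DC (unphysical for a low-pass
medium), and nodes failing a forward-consistency check (the inverted
properties must reproduce the node reflectance within 5% through a
bilinear surrogate of the forward surface — this catches the folded
high-absorption region) are flagged NaN rather than extrapolated. Lookup
is bilinear in log-reflectance; any query touching a flagged node, leaving
the grids, or violating AC < DC is reported undetermined, never fabricated.
Roundtrip (predict then invert) recovers interior properties to well
within 2%.

## Image pipeline

Frames are normalized by exposure, demodulated by 2D Fourier filtering
(modulation along the image's second axis), calibrated against a reference
frame via `Rd = (M / M_ref) Rd_ref_pred`, and inverted per pixel. Two
filter modes: smoothed disc notches (Gaussian sigma = 1 frequency pixel,
radius 0.25 fx floored at 2.5 frequency bins per axis with a hard-zero
core — without the floor a peak one bin off a small image's grid leaks
~40% through the softened edge) for well-separated spectra; and separable
raised-cosine masks (narrow band around the AC peak along the modulation
axis, wide lowpass across it) for low fx. The AC image is twice the
magnitude of the inverse transform of the isolated positive lobe, so a
pure cosine of amplitude a yields a. Both modes recover analytic
sinusoids to machine precision away from edges and keep a 10% second
harmonic below 1% leakage.

The inverse Monte Carlo fitter estimates (mua, mus') from two measured
energy fractions by bounded nonnegative least squares over the seeded slab
simulator (thin-sample R/T, or thick-sample R plus thin-sample
transflectance 1 - A). The per-iteration seed is fixed, making the
objective deterministic; finite differences use a 10% relative step, well
above the Monte Carlo roughness at the default 2e4-photon budget. The
starting point is a diffusion-approximation closed form: reduced albedo
read off the semi-infinite diffusion reflectance curve, transport
coefficient from the effective-attenuation decay of the transmittance.
Parameter recovery on synthetic measurements is within 5% relative; a
zero-absorption truth drives the estimate to the nonnegativity bound.

## Synthetic data

The phantom grid crosses four absorption levels with four scattering
levels per imaging channel (850, 625, 545, 395 nm), reproducing the
published 16-phantom target table exactly (all reduced albedos match the
printed two-decimal values). Scenes are rendered from the wMC-predicted
reflectance pair of the phantom: intensity = exposure x gain(x, y) x
0.5 (R_DC + R_AC cos(2 pi fx x + phase)), with a smooth radial gain field
(+-5% by default), plus shot-like Gaussian noise with sigma =
0.002 sqrt(signal) — the shot-noise limit of a scientific CMOS exposed
near full well (~200:1 at mid-scale). The reference frame uses phantom
11's properties (mid-grid, diffusely scattering) under the same gain and
pattern; a reflectance-standard reference is emulated by passing a flat
0.99/0.99 predicted pair instead. Polarization is represented only as the
choice of which SPF renders a scene (ttHG for unpolarized, an stHG for
cross-polarized, encoding the suppression of immediately backscattered
light) — there is no vector transport.

Goniometry generation applies the forward Snell distortion, solid-angle
and clear-host-transmission scaling, a clear-sample offset rising toward
180 degrees, and multiplicative noise, emitting the matching clear scan;
positive/negative-angle repeats are averaged as in the measurement
protocol.

What the generators do not emulate: camera PSF/MTF and read noise, surface
roughness, autofluorescence, spectral width of the channels, true
polarized transport. Closure tests therefore demonstrate the correctness
and self-consistency of the modelling chain — not field accuracy on real
tissue.

## Accuracy bookkeeping

ROI statistics are the mean and linearly interpolated quartiles over
determined pixels; an ROI with more than 2% undetermined pixels is flagged
omitted. Error is mean absolute percent error against ground truth.
Summary tables average channel errors per (SPF, polarization, quantity)
cell with omitted entries excluded. On synthetic studies the machinery
reproduces the expected structure: matched-SPF errors of a few percent;
with a mismatched SPF the reduced-scattering error pivots about the
reference phantom's scattering value (overestimated below, underestimated
above, +45% to -7% across the scattering groups at fx = 1.0); and
high-absorption scenes develop undetermined pixels as the AC reflectance
approaches DC.

## Known limitations

* The wMC similarity scaling is exact for the random-walk geometry but the
  base run fixes the refractive index; records are not transferable across
  n.
* The anisotropic filter parameterization follows the cited concept
  (directional tolerance), not the original implementation's exact widths;
  widths are configurable.
* The goniometer backward lobe is information-poor by instrument geometry;
  gb uncertainty ~0.02 per unit relative noise is intrinsic.
* The low-absorption corner (mua <~ 0.05 mm^-1 with weak AC sensitivity)
  is noise-limited in per-pixel MAPE regardless of model correctness.
* Polarization is a labeling device; no Stokes-vector transport is
  attempted.
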