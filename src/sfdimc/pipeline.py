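"""From patterned-illumination images to optical-property maps.

The single-phase SFDI processing chain:

1. **Demodulation** — a 2D Fourier-domain filtering step splits each frame
   into a DC intensity image and an AC amplitude image at the projected
   spatial frequency, using either generalized spectral notch filters
   (well-separated peaks, high ``fx``) or anisotropic separable filters
   (low ``fx``), with notches at the pattern harmonics.
2. **Calibration** — the demodulated sample intensities are ratioed against
   a reference measurement of known optical properties and scaled by the
   model-predicted reference reflectance:
   ``Rd = (M / M_ref) * Rd_ref_pred``, channel-wise for DC and AC.
3. **Inversion** — each pixel's (DC, AC) reflectance pair is interpolated
   within a precomputed lookup table to per-pixel ``(mua, mus')``; pixels
   whose AC reflectance reaches or exceeds the DC value, or that leave the
   table, are marked undetermined.

The module also provides the inverse Monte Carlo fitter used to establish
ground-truth optical properties of physical samples from integrating-sphere
style measurables (thin-sample R/T, or thick-sample R plus transflectance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

from sfdimc.forward import InversionLUT
from sfdimc.phase_functions import InverseCdfTable
from sfdimc.transport import ReflectancePair, TransportConfig, simulate_slab

__all__ = [
    "DemodulatedImage",
    "PropertyMap",
    "fourier_demod_single",
    "calibrate",
    "invert_map",
    "inverse_mc_fit",
]


@dataclass
class DemodulatedImage:
    """Per-pixel demodulated DC intensity and AC amplitude at one ``fx``."""

    m_dc: np.ndarray
    m_ac: np.ndarray
    fx: float
    pixel_pitch: float
    exposure_normalized: bool = True

    def __post_init__(self) -> None:
        if self.m_dc.shape != self.m_ac.shape:
            raise ValueError("DC and AC images must share a shape")


@dataclass
class PropertyMap:
    """Per-pixel absorption and reduced scattering maps with a failure mask."""

    mua_map: np.ndarray
    mus_prime_map: np.ndarray
    undetermined_mask: np.ndarray

    def save_tiff(self, prefix) -> None:
        """Write 32-bit float TIFF pairs plus a uint8 mask."""
        import tifffile

        tifffile.imwrite(f"{prefix}_mua.tif", self.mua_map.astype(np.float32))
        tifffile.imwrite(f"{prefix}_musp.tif", self.mus_prime_map.astype(np.float32))
        tifffile.imwrite(
            f"{prefix}_undetermined.tif", self.undetermined_mask.astype(np.uint8)
        )


def _freq_grids(shape, pixel_pitch):
    fv = np.fft.fftfreq(shape[0], d=pixel_pitch)
    fu = np.fft.fftfreq(shape[1], d=pixel_pitch)
    return np.meshgrid(fv, fu, indexing="ij")


def _disc_notch(fv, fu, center_u, center_v, radius, sigma_px):
    """Smoothed inverted disc notch at one frequency-space location.

    The notch radius is floored at 2.5 frequency bins per axis so the
    targeted peak is fully suppressed regardless of the image's spectral
    resolution; after Gaussian smoothing the core is re-zeroed so no peak
    energy leaks through the softened edge.
    """
    du = abs(fu[0, 1] - fu[0, 0])
    dv = abs(fv[1, 0] - fv[0, 0])
    ru = max(radius, 2.5 * du)
    rv = max(radius, 2.5 * dv)
    d2 = ((fu - center_u) / ru) ** 2 + ((fv - center_v) / rv) ** 2
    mask = gaussian_filter((d2 > 1.0).astype(float), sigma=sigma_px, mode="wrap")
    mask[d2 <= 0.25] = 0.0
    return mask


def _raised_cosine_band(f, center, half_width, taper):
    """1D raised-cosine bandpass around ``center``; 1 inside, tapering to 0."""
    d = np.abs(f - center)
    out = np.zeros_like(d)
    out[d <= half_width] = 1.0
    edge = (d > half_width) & (d < half_width + taper)
    out[edge] = 0.5 * (1.0 + np.cos(np.pi * (d[edge] - half_width) / taper))
    return out


def fourier_demod_single(
    image: np.ndarray,
    fx: float,
    pixel_pitch: float,
    mode: str = "notch",
    harmonics_to_remove: int = 2,
    notch_radius_frac: float = 0.25,
    ac_band_frac: float = 0.15,
) -> DemodulatedImage:
    """Single-phase Fourier-domain demodulation of one patterned frame.

    The modulation axis is the image's second (column) axis.  In ``notch``
    mode, smoothed (Gaussian, sigma = 1 frequency pixel) disc notches
    remove: for the DC image, the +-AC peaks and the first harmonic pair;
    for the AC image, the DC peak, the negative AC peak, and the first
    ``harmonics_to_remove`` harmonic pairs.  In ``anisotropic`` mode,
    separable raised-cosine masks pass a narrow band around the AC peak
    along the modulation axis and a wide band along the orthogonal axis.
    The AC amplitude is the magnitude of the inverse transform of the
    isolated positive-frequency lobe, doubled for the removed conjugate.
    """
    image = np.asarray(image, dtype=float)
    nyquist = 0.5 / pixel_pitch
    if fx >= nyquist:
        raise ValueError(f"fx={fx} at or beyond the Nyquist frequency {nyquist:.3g}")
    if fx > 0.5 * nyquist:
        raise ValueError(
            f"fx={fx} not resolvable: need at least 4 pixels per period"
        )
    fv, fu = _freq_grids(image.shape, pixel_pitch)
    spectrum = np.fft.fft2(image)

    radius = notch_radius_frac * fx
    if mode == "notch":
        mask_dc = np.ones(image.shape)
        for sign in (+1, -1):
            for h in (1, 2):  # AC peak and first harmonic pair
                if h * fx < nyquist:
                    mask_dc *= _disc_notch(fv, fu, sign * h * fx, 0.0, radius, 1.0)
        mask_ac = _disc_notch(fv, fu, 0.0, 0.0, radius, 1.0)  # DC peak
        mask_ac *= _disc_notch(fv, fu, -fx, 0.0, radius, 1.0)  # conjugate
        for h in range(2, 2 + harmonics_to_remove):
            for sign in (+1, -1):
                if h * fx < nyquist:
                    mask_ac *= _disc_notch(fv, fu, sign * h * fx, 0.0, radius, 1.0)
        # suppress the full negative-frequency half so only +fx remains
        mask_ac *= fu > 0.0
    elif mode == "anisotropic":
        taper = ac_band_frac * fx
        lp_orth = _raised_cosine_band(fv, 0.0, 0.6 * nyquist, 0.3 * nyquist)
        band_dc = _raised_cosine_band(fu, 0.0, 0.5 * fx, 0.35 * fx)
        mask_dc = band_dc * lp_orth
        band_ac = _raised_cosine_band(fu, fx, ac_band_frac * fx, taper)
        mask_ac = band_ac * lp_orth
        for h in range(2, 2 + harmonics_to_remove):
            for sign in (+1, -1):
                if h * fx < nyquist:
                    mask_ac *= _disc_notch(fv, fu, sign * h * fx, radius, radius, 1.0)
    else:
        raise ValueError("mode must be 'notch' or 'anisotropic'")

    m_dc = np.abs(np.fft.ifft2(spectrum * mask_dc).real)
    m_ac = 2.0 * np.abs(np.fft.ifft2(spectrum * mask_ac))
    return DemodulatedImage(m_dc=m_dc, m_ac=m_ac, fx=fx, pixel_pitch=pixel_pitch)


def calibrate(
    sample: DemodulatedImage,
    reference: DemodulatedImage,
    rd_ref_pred: ReflectancePair,
) -> ReflectancePair:
    """Reference calibration: ``Rd = (M / M_ref) * Rd_ref_pred`` per channel.

    Pixels where the reference intensity is zero or negative are set NaN
    (masked) rather than divided through.
    """
    if sample.m_dc.shape != reference.m_dc.shape:
        raise ValueError("sample and reference images must share a shape")
    out = []
    for m, mref, rpred in (
        (sample.m_dc, reference.m_dc, rd_ref_pred.dc),
        (sample.m_ac, reference.m_ac, rd_ref_pred.ac),
    ):
        valid = mref > 0.0
        rd = np.full(m.shape, np.nan)
        rd[valid] = m[valid] / mref[valid] * rpred
        out.append(rd)
    return ReflectancePair(dc=out[0], ac=out[1], fx=sample.fx)


def invert_map(rd: ReflectancePair, lut: InversionLUT) -> PropertyMap:
    """Per-pixel LUT inversion of a calibrated reflectance image pair.

    Bilinear interpolation in log-reflectance coordinates; pixels with
    ``AC >= DC``, values off the LUT grids, NaN inputs, or flagged LUT
    nodes become undetermined (never an error).
    """
    if abs(rd.fx - lut.fx) > 1e-9:
        raise ValueError(
            f"reflectance fx={rd.fx} does not match LUT fx={lut.fx}"
        )
    dc = np.asarray(rd.dc, dtype=float)
    ac = np.asarray(rd.ac, dtype=float)
    bad_in = ~np.isfinite(dc) | ~np.isfinite(ac)
    dc_q = np.where(bad_in, lut.dc_grid[0], dc)
    ac_q = np.where(bad_in, lut.ac_grid[0], ac)
    mua, mus, undet = lut.lookup(dc_q, ac_q)
    undet = undet | bad_in
    mua = np.where(undet, np.nan, mua)
    mus = np.where(undet, np.nan, mus)
    return PropertyMap(mua_map=mua, mus_prime_map=mus, undetermined_mask=undet)


def _effective_reflection_param(n: float) -> float:
    """Internal-reflection parameter A of the diffusion approximation."""
    r_eff = 0.0636 * n + 0.668 + 0.71 / n - 1.44 / n**2
    return (1.0 + r_eff) / (1.0 - r_eff)


def _diffusion_seed(r_meas, t_meas, thickness, n_medium):
    """Closed-form diffusion-approximation starting point for the iMC fit.

    The reduced albedo is read off the semi-infinite diffusion reflectance
    curve and the transport coefficient from the Beer-Lambert-like decay of
    the total transmittance at the effective attenuation coefficient.
    """
    a_grid = np.linspace(0.05, 0.999, 400)
    A = _effective_reflection_param(n_medium)
    mu_ratio = np.sqrt(3.0 * (1.0 - a_grid))  # mu_eff / mu_tr
    rd_curve = 3.0 * A * a_grid / ((mu_ratio + 1.0) * (mu_ratio + 3.0 * A))
    a0 = float(np.interp(np.clip(r_meas, rd_curve[0], rd_curve[-1]), rd_curve, a_grid))
    mu_eff = -np.log(np.clip(t_meas, 1e-6, 0.999)) / thickness
    mu_tr = mu_eff / max(np.sqrt(3.0 * (1.0 - a0)), 1e-3)
    mua0 = max((1.0 - a0) * mu_tr, 1e-3)
    mus0 = max(a0 * mu_tr, 0.05)
    return mua0, mus0


def inverse_mc_fit(
    measurements: Sequence[float],
    mode: str,
    spf: InverseCdfTable,
    g1: float,
    thin_thickness: float = 1.0,
    thick_thickness: float = 17.0,
    n_medium: float = 1.56,
    n_photons: int = 20_000,
    seed: int = 0,
    init: Optional[tuple] = None,
    max_nfev: int = 60,
):
    """Inverse Monte Carlo: fit ``(mua, mus')`` to measured energy fractions.

    ``mode='thin_RT'`` fits the (diffuse reflectance, transmittance) pair of
    a thin sample (1 mm beam, 2 mm cyclic lateral domain);
    ``mode='thick_R_plus_transflectance'`` fits the thick-sample diffuse
    reflectance (4 mm beam) together with the thin-sample transflectance
    ``1 - A``.  The forward model is the seeded slab simulator with a fixed
    per-iteration seed, making the objective deterministic.  Estimates are
    constrained non-negative.  Returns ``(mua, mus_prime, result)`` with the
    scipy least-squares result for diagnostics.
    """
    meas = np.asarray(measurements, dtype=float)
    if meas.size != 2 or np.any(meas < 0.0) or np.any(meas > 1.0):
        raise ValueError("measurements must be two fractions in [0, 1]")
    if mode not in ("thin_RT", "thick_R_plus_transflectance"):
        raise ValueError(f"unknown mode {mode!r}")

    def forward(mua, mus_prime):
        base = dict(spf=spf, n_medium=n_medium, t_max=50.0, seed=seed)
        if mode == "thin_RT":
            cfg = TransportConfig.from_reduced(
                mua=mua, mus_prime=mus_prime, g1=g1, n_photons=n_photons, **base
            )
            res = simulate_slab(cfg, thin_thickness, beam_diameter=1.0, lateral_period=2.0)
            return np.array([res.diffuse_reflectance, res.transmittance])
        cfg_thick = TransportConfig.from_reduced(
            mua=mua, mus_prime=mus_prime, g1=g1, n_photons=n_photons, **base
        )
        res_thick = simulate_slab(
            cfg_thick, thick_thickness, beam_diameter=4.0, lateral_period=8.0
        )
        cfg_thin = TransportConfig.from_reduced(
            mua=mua, mus_prime=mus_prime, g1=g1, n_photons=n_photons, **base
        )
        res_thin = simulate_slab(cfg_thin, thin_thickness, beam_diameter=1.0, lateral_period=2.0)
        return np.array([res_thick.diffuse_reflectance, res_thin.transflectance])

    if init is None:
        if mode == "thin_RT":
            init = _diffusion_seed(meas[0], meas[1], thin_thickness, n_medium)
        else:
            init = _diffusion_seed(meas[0], 1.0 - meas[1] + 1e-3, thin_thickness, n_medium)

    def residuals(p):
        return forward(p[0], p[1]) - meas

    result = least_squares(
        residuals,
        x0=np.asarray(init, dtype=float),
        bounds=([0.0, 1e-3], [30.0, 30.0]),
        diff_step=0.1,
        xtol=1e-3,
        ftol=1e-4,
        gtol=None,
        max_nfev=max_nfev,
    )
    if not result.success and result.status <= 0:
        raise RuntimeError(f"inverse MC fit did not converge: {result.message}")
    mua, mus_prime = result.x
    return float(mua), float(mus_prime), result
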