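"""Goniometer scan reduction and two-term Henyey-Greenstein fitting.

A goniometric measurement of a thin, single-scattering sample records the
scattered intensity at a set of detector angles.  Before a phase function
can be fitted, the raw scan must be (i) normalized by the detector solid
angle and the clear-host transmission, (ii) corrected for host-surface
scattering by subtracting a matched clear-sample scan, and (iii) corrected
for refraction at the sample-air interface, which compresses the angles
actually sampled inside a high-index host.  The corrected per-steradian
data are then split into a forward lobe (detector angles below the occluded
band) and a backward lobe, each fitted to a scaled stHG function by weighted
nonlinear least squares; the two scale factors set the ttHG mixing fraction
``alpha = s_f / (s_f + s_b)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from sfdimc.phase_functions import SthgParams, TtHGParams, eval_sthg

__all__ = [
    "GoniometryDataset",
    "MfpEstimate",
    "refraction_correct",
    "detector_solid_angle",
    "normalize_and_correct",
    "fit_sthg_section",
    "combine_tthg",
    "estimate_optical_thickness",
    "fit_goniometry",
]

# detector angles in (60, 120) degrees are occluded by the sample holder
FORWARD_MAX_DEG = 60.0
BACKWARD_MIN_DEG = 120.0


@dataclass
class GoniometryDataset:
    """One goniometer scan plus the instrument geometry needed to reduce it.

    ``angles_meas`` are detector angles in degrees (0 = unscattered beam
    direction); ``intensity`` is the measured normalized intensity at each
    angle.  ``n_sample``/``n_det`` are the refractive indices on the sample
    and detector sides; aperture diameter, detector distance, and sample
    thickness are in millimetres.
    """

    angles_meas: np.ndarray
    intensity: np.ndarray
    n_sample: float = 1.556
    n_det: float = 1.0
    aperture_diameter: float = 8.2
    detector_distance: float = 128.0
    sample_thickness: float = 0.33

    def __post_init__(self) -> None:
        self.angles_meas = np.asarray(self.angles_meas, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.angles_meas.shape != self.intensity.shape:
            raise ValueError("angles and intensities must align")
        if np.any((self.angles_meas < 0.0) | (self.angles_meas > 180.0)):
            raise ValueError("detector angles must lie in [0, 180] degrees")
        in_band = (self.angles_meas > FORWARD_MAX_DEG) & (
            self.angles_meas < BACKWARD_MIN_DEG
        )
        if np.any(in_band):
            raise ValueError(
                "angles within the occluded (60, 120) degree band are not measurable"
            )
        if not self.n_sample > self.n_det > 0.0:
            raise ValueError("requires n_sample > n_det > 0")

    def to_csv(self) -> str:
        """Two-column CSV with a key-value metadata header."""
        buf = io.StringIO()
        for key in (
            "n_sample",
            "n_det",
            "aperture_diameter",
            "detector_distance",
            "sample_thickness",
        ):
            buf.write(f"# {key} = {getattr(self, key)}\n")
        buf.write("angle_deg,intensity\n")
        for a, v in zip(self.angles_meas, self.intensity):
            buf.write(f"{a:.6g},{v:.10g}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "GoniometryDataset":
        meta = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = float(val)
            elif not line.startswith("angle"):
                a, v = line.split(",")
                rows.append((float(a), float(v)))
        arr = np.array(rows)
        return cls(angles_meas=arr[:, 0], intensity=arr[:, 1], **meta)


@dataclass(frozen=True)
class MfpEstimate:
    """Scattering-coefficient and optical-thickness bounds for a thin sample."""

    mus_low: float
    mus_high: float
    mfp_low: float
    mfp_high: float


def refraction_correct(theta_meas, n_sample: float, n_det: float = 1.0):
    """Map detector angles to in-sample scattering angles via Snell's law.

    ``theta_scat = asin((n_det/n_sample) sin(theta_meas))`` for the forward
    branch (below 90 deg) and ``180 - asin(...)`` for the backward branch.
    Angles in degrees.  90 deg lies on neither branch and raises.
    """
    theta = np.asarray(theta_meas, dtype=float)
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    if np.any((theta < 0.0) | (theta > 180.0)):
        raise ValueError("theta_meas must lie in [0, 180] degrees")
    if np.any(theta == 90.0):
        raise ValueError("theta_meas = 90 deg lies on neither refraction branch")
    if n_sample < n_det:
        raise ValueError("requires n_sample >= n_det")
    inner = np.degrees(np.arcsin((n_det / n_sample) * np.sin(np.radians(theta))))
    out = np.where(theta < 90.0, inner, 180.0 - inner)
    return float(out[0]) if scalar else out


def detector_solid_angle(aperture_diameter: float, detector_distance: float) -> float:
    """Solid angle of a circular aperture, planar-disc approximation.

    ``Omega = pi (d/2)^2 / D^2`` steradians; valid for ``d << D``.
    """
    if aperture_diameter < 0.0 or detector_distance <= 0.0:
        raise ValueError("aperture and distance must be positive")
    if aperture_diameter >= detector_distance:
        import warnings

        warnings.warn(
            "aperture diameter comparable to detector distance; "
            "planar-disc solid-angle approximation is invalid",
            stacklevel=2,
        )
    return np.pi * (aperture_diameter / 2.0) ** 2 / detector_distance**2


def normalize_and_correct(
    raw: GoniometryDataset,
    clear_total_transmission: float,
    clear_angular: np.ndarray,
):
    """Convert a raw scan into per-steradian SPF samples.

    Divides by the detector solid angle and the clear-host total
    transmission, then subtracts the identically normalized clear-sample
    angular scan at every non-zero angle (surface-scatter correction).
    Negative corrected values are floored at zero and flagged.

    Returns ``(values, floored)``: per-steradian samples aligned with
    ``raw.angles_meas`` and a boolean mask of floored entries.
    """
    if not 0.0 < clear_total_transmission <= 1.0:
        raise ValueError("clear_total_transmission must lie in (0, 1]")
    clear = np.asarray(clear_angular, dtype=float)
    if clear.shape != raw.angles_meas.shape:
        raise ValueError("clear-sample scan is misaligned with the raw angle grid")
    omega = detector_solid_angle(raw.aperture_diameter, raw.detector_distance)
    scale = 1.0 / (omega * clear_total_transmission)
    values = raw.intensity * scale
    nonzero = raw.angles_meas != 0.0
    values = np.where(nonzero, values - clear * scale, values)
    floored = values < 0.0
    return np.where(floored, 0.0, values), floored


def _section_fit(angles_scat_deg, values, g_bounds, g_starts):
    cos_t = np.cos(np.radians(np.asarray(angles_scat_deg, dtype=float)))
    y = np.asarray(values, dtype=float)
    keep = y > 0.0
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive samples in the section")
    cos_t, y = cos_t[keep], y[keep]
    # weight rule: max measurement in the section over each measurement,
    # applied to squared residuals (sqrt in the residual vector)
    sqrt_w = np.sqrt(y.max() / y)

    def residuals(p):
        g, log_s = p
        return sqrt_w * (np.exp(log_s) * eval_sthg(SthgParams(g), cos_t) - y)

    best = None
    for g0 in g_starts:
        s0 = np.log(max(y.mean() / max(float(eval_sthg(SthgParams(g0), cos_t).mean()), 1e-300), 1e-12))
        res = least_squares(
            residuals,
            x0=[g0, s0],
            bounds=([g_bounds[0], -50.0], [g_bounds[1], 50.0]),
            method="trf",
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError(f"stHG section fit failed to converge: {best}")
    g, log_s = best.x
    return float(g), float(np.exp(log_s))


def fit_sthg_section(angles_scat, values, section: str):
    """Fit ``s * stHG(g)`` to one section of corrected goniometry data.

    ``section`` is ``"forward"`` (g constrained to [0, 1)) or ``"backward"``
    (g in (-1, 0]).  Angles are refraction-corrected scattering angles in
    degrees.  Returns ``(g, s)``.
    """
    if section == "forward":
        return _section_fit(angles_scat, values, (0.0, 0.999), (0.5, 0.8, 0.95))
    if section == "backward":
        return _section_fit(angles_scat, values, (-1.0 + 1e-9, 0.0), (-1e-6, -0.3))
    raise ValueError("section must be 'forward' or 'backward'")


def combine_tthg(s_f: float, s_b: float, g_f: float, g_b: float) -> TtHGParams:
    """Merge forward/backward stHG fits: ``alpha = s_f / (s_f + s_b)``."""
    if s_f < 0.0 or s_b < 0.0 or (s_f == 0.0 and s_b == 0.0):
        raise ValueError("scale factors must be non-negative and not both zero")
    return TtHGParams(alpha=s_f / (s_f + s_b), gf=g_f, gb=g_b)


def estimate_optical_thickness(
    mus_prime: float, g_low: float, g_high: float, thickness: float
) -> MfpEstimate:
    """Bound the scattering coefficient and sample optical thickness.

    Given a reduced scattering coefficient and a literature anisotropy range,
    ``mus = mus_prime / (1 - g)`` at each end, and the optical thickness in
    scattering mean free paths is ``thickness * mus``.
    """
    if not 0.0 < g_low <= g_high < 1.0:
        raise ValueError("requires 0 < g_low <= g_high < 1")
    if thickness <= 0.0 or mus_prime <= 0.0:
        raise ValueError("thickness and mus_prime must be positive")
    mus_low = mus_prime / (1.0 - g_low)
    mus_high = mus_prime / (1.0 - g_high)
    return MfpEstimate(
        mus_low=mus_low,
        mus_high=mus_high,
        mfp_low=thickness * mus_low,
        mfp_high=thickness * mus_high,
    )


def fit_goniometry(
    raw: GoniometryDataset,
    clear_total_transmission: float,
    clear_angular: np.ndarray,
    include_zero_angle: bool = True,
    n_refine: int = 3,
) -> TtHGParams:
    """Full reduction: correct a raw scan and fit the ttHG phase function.

    The forward/backward split is applied in detector coordinates (below
    60 deg and above 120 deg, matching the instrument occlusion band).  The
    0 deg point anchors the forward-lobe scale, without which the (g, s)
    pair is nearly degenerate over the refraction-compressed angle range;
    it is included by default and should be dropped (``include_zero_angle
    =False``) when the scan retains an unscattered-beam contribution.

    Each section of the data still contains the tail of the *other* lobe
    (the isotropic backscatter floor is comparable to the forward lobe at
    30-35 deg), which biases independent section fits.  After the initial
    fits, ``n_refine`` rounds of cross-subtraction remove the fitted
    opposite-lobe contribution from each section before refitting; the
    final scale factors feed the usual ``alpha = s_f/(s_f+s_b)`` mix.
    """
    values, _ = normalize_and_correct(raw, clear_total_transmission, clear_angular)
    theta_scat = refraction_correct(raw.angles_meas, raw.n_sample, raw.n_det)
    fwd = raw.angles_meas < FORWARD_MAX_DEG
    if not include_zero_angle:
        fwd &= raw.angles_meas > 0.0
    bwd = raw.angles_meas > BACKWARD_MIN_DEG
    cos_f = np.cos(np.radians(theta_scat[fwd]))
    cos_b = np.cos(np.radians(theta_scat[bwd]))
    g_f, s_f = fit_sthg_section(theta_scat[fwd], values[fwd], "forward")
    g_b, s_b = fit_sthg_section(theta_scat[bwd], values[bwd], "backward")
    for _ in range(n_refine):
        resid_b = values[bwd] - s_f * eval_sthg(SthgParams(g_f), cos_b)
        g_b, s_b = fit_sthg_section(theta_scat[bwd], np.clip(resid_b, 0.0, None), "backward")
        resid_f = values[fwd] - s_b * eval_sthg(SthgParams(g_b), cos_f)
        g_f, s_f = fit_sthg_section(theta_scat[fwd], np.clip(resid_f, 0.0, None), "forward")
    return combine_tthg(s_f, s_b, g_f, g_b)
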