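"""Synthetic inputs for the SFDI modelling stack.

Three generators cover everything the pipeline consumes, at desk scale and
with ground truth attached:

* the 16-phantom optical-property grid (four absorption levels crossed
  with four scattering levels, specified per imaging channel at 850, 625,
  545, and 395 nm);
* rendered SFDI scenes: sinusoidally patterned frames whose underlying
  reflectance comes from a white-MC forward model, with a smooth
  illumination gain field, exposure scaling, and shot-like noise;
* goniometer scans: a known two-term Henyey-Greenstein phase function
  pushed through the forward refraction distortion, solid-angle scaling,
  a clear-host surface-scatter offset, and multiplicative noise — exactly
  the distortions the goniometry reduction must undo.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from sfdimc.forward import WhiteMCRecord, predict_pair
from sfdimc.goniometry import GoniometryDataset, detector_solid_angle, refraction_correct
from sfdimc.phase_functions import TtHGParams, eval_tthg
from sfdimc.transport import ReflectancePair

__all__ = [
    "CHANNELS",
    "PhantomSpec",
    "SceneConfig",
    "PhantomScene",
    "make_phantom_table",
    "render_scene",
    "synth_goniometry",
]

CHANNELS = ("850", "625", "545", "395")

# per-channel absorption groups (rows of the phantom grid) and reduced
# scattering groups (columns), mm^-1
_MUA_GROUPS = {
    "850": (0.015, 0.05, 0.075, 0.1),
    "625": (0.03, 0.1, 0.15, 0.3),
    "545": (0.1, 0.3, 1.0, 2.5),
    "395": (0.5, 1.0, 2.5, 5.0),
}
_MUSP_GROUPS = {
    "850": (0.35, 1.0, 1.5, 2.0),
    "625": (0.55, 1.4, 2.2, 3.0),
    "545": (0.8, 1.6, 2.6, 3.5),
    "395": (1.25, 2.5, 4.0, 5.5),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Target optical properties of one phantom, per imaging channel."""

    id: int
    mua: Dict[str, float]
    mus_prime: Dict[str, float]

    @property
    def reduced_albedo(self) -> Dict[str, float]:
        """``alpha' = mus' / (mua + mus')`` per channel."""
        return {
            ch: self.mus_prime[ch] / (self.mua[ch] + self.mus_prime[ch])
            for ch in self.mua
        }


def make_phantom_table() -> list[PhantomSpec]:
    """The 16-phantom target grid: absorption group x scattering group.

    Phantom ``1 + 4*i + j`` carries the ``i``-th absorption level and the
    ``j``-th scattering level of each channel.
    """
    specs = []
    for pid in range(1, 17):
        a_group = (pid - 1) // 4
        s_group = (pid - 1) % 4
        specs.append(
            PhantomSpec(
                id=pid,
                mua={ch: _MUA_GROUPS[ch][a_group] for ch in CHANNELS},
                mus_prime={ch: _MUSP_GROUPS[ch][s_group] for ch in CHANNELS},
            )
        )
    return specs


@dataclass(frozen=True)
class SceneConfig:
    """Rendering parameters for a synthetic SFDI acquisition."""

    fx: float
    phase: float = 0.0
    shape: Tuple[int, int] = (96, 192)
    pixel_pitch: float = 62.0 / 1440.0  # mm per pixel
    gain_amplitude: float = 0.1  # smooth spatial illumination nonuniformity
    # shot-like noise, sigma = scale * sqrt(signal): 0.002 gives ~200:1 SNR at
    # mid-scale intensity, the shot-noise limit of a scientific CMOS exposed
    # near full well
    noise_scale: float = 0.002
    exposure: float = 1.0
    ref_exposure: float = 1.0
    spf_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fx < 0.0:
            raise ValueError("fx must be non-negative")
        if self.exposure <= 0.0 or self.ref_exposure <= 0.0:
            raise ValueError("exposures must be positive")


@dataclass
class PhantomScene:
    """A rendered scene: sample and reference frames plus ground truth."""

    sample_frame: np.ndarray
    reference_frame: np.ndarray
    config: SceneConfig
    truth_mua: float
    truth_mus_prime: float
    truth_pair: ReflectancePair
    reference_props: Tuple[float, float]
    reference_pair: ReflectancePair


def _gain_field(shape, amplitude):
    ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r2 = ((xx - nx / 2) / nx) ** 2 + ((yy - ny / 2) / ny) ** 2
    return 1.0 + amplitude * np.exp(-r2 / (2 * 0.35**2)) - amplitude / 2.0


def _render_frame(pair: ReflectancePair, config: SceneConfig, gain, exposure, rng):
    ny, nx = config.shape
    x_mm = np.arange(nx) * config.pixel_pitch
    pattern = pair.dc + pair.ac * np.cos(2.0 * np.pi * config.fx * x_mm + config.phase)
    frame = exposure * gain * 0.5 * pattern[None, :]
    if config.noise_scale > 0.0:
        frame = frame + rng.normal(
            0.0, config.noise_scale * np.sqrt(np.clip(frame, 0.0, None))
        )
    return frame


def render_scene(
    spec: PhantomSpec,
    channel: str,
    config: SceneConfig,
    wmc: WhiteMCRecord,
    reference_props: Optional[Tuple[float, float]] = None,
) -> PhantomScene:
    """Render a patterned sample frame and matching reference frame.

    Pixel intensity is ``exposure * gain(x, y) * 0.5 * (R_DC + R_AC *
    cos(2 pi fx x + phase))`` with the reflectance pair predicted by the
    supplied white-MC record at the phantom's target properties, plus
    seeded shot-like noise.  The reference defaults to phantom 11's
    properties in the same channel (a mid-grid, diffusely scattering
    phantom).  Both frames share the same gain field, frequency, and
    phase; exposures may differ and are recorded in the scene config.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    mua, musp = spec.mua[channel], spec.mus_prime[channel]
    if reference_props is None:
        ref_spec = make_phantom_table()[10]  # phantom 11
        reference_props = (ref_spec.mua[channel], ref_spec.mus_prime[channel])
    rng = np.random.default_rng(config.seed)
    gain = _gain_field(config.shape, config.gain_amplitude)
    truth_pair = predict_pair(wmc, mua, musp, config.fx)
    ref_pair = predict_pair(wmc, reference_props[0], reference_props[1], config.fx)
    sample = _render_frame(truth_pair, config, gain, config.exposure, rng)
    reference = _render_frame(ref_pair, config, gain, config.ref_exposure, rng)
    return PhantomScene(
        sample_frame=sample,
        reference_frame=reference,
        config=config,
        truth_mua=mua,
        truth_mus_prime=musp,
        truth_pair=truth_pair,
        reference_props=reference_props,
        reference_pair=ref_pair,
    )


_DEFAULT_ANGLES = np.array(
    [0, 10, 20, 30, 40, 50, 60, 120, 130, 140, 150, 160, 170], dtype=float
)


def synth_goniometry(
    truth: TtHGParams,
    n_sample: float = 1.556,
    angles: np.ndarray = _DEFAULT_ANGLES,
    noise: float = 0.02,
    surface_offset: float = 0.01,
    clear_total_transmission: float = 0.92,
    seed: int = 0,
    average_negative_angles: bool = True,
):
    """Generate a distorted goniometer scan from a known phase function.

    For each detector angle the in-sample scattering angle follows the
    refraction correction; the recorded intensity is the true per-steradian
    density there, times the detector solid angle and the clear-host total
    transmission, plus a clear-sample surface-scatter offset that grows
    toward 180 degrees, all under multiplicative Gaussian noise.  By
    default each angle is measured twice (the positive- and negative-angle
    repeats of the goniometer protocol) and the pair is averaged.

    Returns ``(raw, clear_angular, clear_total_transmission)``: the noisy
    scan as a :class:`GoniometryDataset` and the matching noiseless
    clear-sample angular scan.
    """
    angles = np.asarray(angles, dtype=float)
    rng = np.random.default_rng(seed)
    theta_scat = refraction_correct(angles, n_sample)
    density = eval_tthg(truth, np.cos(np.radians(theta_scat)))
    ds_stub = GoniometryDataset(
        angles_meas=angles, intensity=np.zeros_like(angles), n_sample=n_sample
    )
    omega = detector_solid_angle(ds_stub.aperture_diameter, ds_stub.detector_distance)
    # surface scatter artificially boosts collection near 180 degrees
    clear = surface_offset * omega * (0.2 + 0.8 * np.clip((angles - 90) / 90, 0, 1) ** 2)
    clear[angles == 0.0] = 0.0
    raw_values = density * omega * clear_total_transmission + clear
    n_rep = 2 if average_negative_angles else 1
    noisy = raw_values[None, :] * (
        1.0 + noise * rng.standard_normal((n_rep, angles.size))
    )
    raw_values = noisy.mean(axis=0)
    raw = GoniometryDataset(
        angles_meas=angles, intensity=raw_values, n_sample=n_sample
    )
    return raw, clear, clear_total_transmission
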