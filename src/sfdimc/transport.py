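"""Seeded Monte Carlo photon transport in homogeneous turbid media.

Photons are tracked through a continuous (non-voxelized) homogeneous medium
bounded by a top surface at ``z = 0`` and, optionally, a bottom surface at
``z = thickness``.  Step lengths are exponential with rate ``mus``;
deflection cosines are drawn from an arbitrary scattering phase function via
a tabulated inverse CDF; azimuth is uniform.  Boundaries apply unpolarized
Fresnel coefficients with probabilistic reflection, and the incident beam
undergoes probabilistic specular reflection at normal incidence.  Absorption
is applied as continuous weight decay along the path (Beer-Lambert), with
the deposited weight accounted exactly, so the energy ledger

    launched = top escape + bottom escape + absorbed + in-flight at the
               time cap

closes to floating-point precision.  Time of flight accumulates as
``pathlength * n / c`` with no discretization.

Three source geometries are provided: a pencil beam on a half-space (the
white Monte Carlo source), a finite beam on a slab with cyclic lateral
boundaries (reflectance/transmittance), and a sinusoidally patterned source
with cyclic boundaries (the direct SFDI simulation used to validate the
white-MC forward model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from sfdimc.phase_functions import InverseCdfTable

__all__ = [
    "C_MM_PER_NS",
    "TransportConfig",
    "ExitRecords",
    "SlabResult",
    "PatternProfile",
    "ReflectancePair",
    "propagate_pencil",
    "simulate_slab",
    "simulate_sfdi_pattern",
    "demod_three_phase",
    "penetration_depth",
]

C_MM_PER_NS = 299.792458  # speed of light in vacuum, mm/ns

# exit side codes written by the kernel
SIDE_TOP = 0
SIDE_BOTTOM = 1
SIDE_TIME_CAP = 2
SIDE_WEIGHT_CUT = 3
SIDE_SPECULAR = 4

# source modes
_SRC_PENCIL = 0
_SRC_PATTERN = 1
_SRC_DISC = 2


@dataclass(frozen=True)
class TransportConfig:
    """Medium, phase function, and run-control parameters for one simulation.

    ``mus`` is the scattering coefficient (mm^-1); use
    :meth:`from_reduced` to specify a reduced scattering coefficient and
    anisotropy instead.  ``t_max`` (ns) caps the photon time of flight;
    capped photons are dropped and counted.  ``weight_cutoff`` terminates
    photons in absorbing media once their weight is negligible, with the
    residual booked as absorbed.
    """

    mua: float
    mus: float
    spf: InverseCdfTable
    n_medium: float = 1.56
    n_outside: float = 1.0
    t_max: float = 300.0
    n_photons: int = 100_000
    seed: int = 0
    g1: Optional[float] = None
    weight_cutoff: float = 1e-7

    def __post_init__(self) -> None:
        if self.mua < 0.0:
            raise ValueError("mua must be non-negative")
        if self.mus < 0.0:
            raise ValueError("mus must be non-negative")
        if self.t_max <= 0.0:
            raise ValueError("t_max must be positive")
        if self.n_photons < 1:
            raise ValueError("n_photons must be at least 1")

    @classmethod
    def from_reduced(
        cls, mua: float, mus_prime: float, g1: float, spf: InverseCdfTable, **kw
    ) -> "TransportConfig":
        """Build a config from ``(mua, mus_prime)`` with ``mus = mus'/(1-g1)``."""
        if not -1.0 < g1 < 1.0:
            raise ValueError("g1 must lie in (-1, 1)")
        return cls(mua=mua, mus=mus_prime / (1.0 - g1), spf=spf, g1=g1, **kw)

    @property
    def mus_prime(self) -> float:
        if self.g1 is None:
            raise ValueError("g1 was not provided; reduced scattering is undefined")
        return self.mus * (1.0 - self.g1)

    @property
    def speed(self) -> float:
        """Speed of light in the medium, mm/ns."""
        return C_MM_PER_NS / self.n_medium


@dataclass
class ExitRecords:
    """Per-photon exit tallies from a transport run (struct-of-arrays).

    Every launched photon contributes exactly one record; ``side``
    distinguishes top escape, bottom escape, the time cap, the weight
    cutoff, and specular reflection at entry.  ``radius`` is the lateral
    distance from the source axis at exit, ``time_of_flight`` in ns,
    ``weight`` the surviving photon weight.
    """

    x: np.ndarray
    y: np.ndarray
    time_of_flight: np.ndarray
    weight: np.ndarray
    side: np.ndarray
    absorbed: float
    n_launched: int
    config: TransportConfig

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def escaped_top(self) -> "ExitRecords":
        """View restricted to photons that escaped through the top surface."""
        m = self.side == SIDE_TOP
        return replace_arrays(self, m)

    def to_hdf5(self, path) -> None:
        """Chunked binary container with config and seed metadata embedded."""
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("x", "y", "time_of_flight", "weight", "side"):
                f.create_dataset(name, data=getattr(self, name), chunks=True,
                                 compression="gzip")
            f.attrs.update(
                {
                    "absorbed": self.absorbed,
                    "n_launched": self.n_launched,
                    "mua": self.config.mua,
                    "mus": self.config.mus,
                    "n_medium": self.config.n_medium,
                    "n_outside": self.config.n_outside,
                    "t_max": self.config.t_max,
                    "seed": self.config.seed,
                    "spf_label": self.config.spf.label,
                }
            )

    def ledger(self) -> dict:
        """Weight bookkeeping by fate, as fractions of launched weight."""
        n = float(self.n_launched)
        out = {}
        for name, code in [
            ("top", SIDE_TOP),
            ("bottom", SIDE_BOTTOM),
            ("time_cap", SIDE_TIME_CAP),
            ("specular", SIDE_SPECULAR),
        ]:
            out[name] = float(self.weight[self.side == code].sum()) / n
        out["absorbed"] = self.absorbed / n
        return out


def replace_arrays(rec: ExitRecords, mask: np.ndarray) -> ExitRecords:
    return ExitRecords(
        x=rec.x[mask],
        y=rec.y[mask],
        time_of_flight=rec.time_of_flight[mask],
        weight=rec.weight[mask],
        side=rec.side[mask],
        absorbed=rec.absorbed,
        n_launched=rec.n_launched,
        config=rec.config,
    )


@dataclass(frozen=True)
class ReflectancePair:
    """(DC, AC) diffuse reflectance at a stated spatial frequency.

    ``dc`` and ``ac`` may be scalars or per-pixel arrays; ``fx`` in mm^-1.
    """

    dc: object
    ac: object
    fx: float


@dataclass(frozen=True)
class SlabResult:
    """Energy partition of a finite-slab run, as fractions of launched weight."""

    reflectance: float  # top escape, specular included
    transmittance: float
    absorbed: float
    dropped: float  # in-flight weight at the time cap
    specular: float

    @property
    def diffuse_reflectance(self) -> float:
        return self.reflectance - self.specular

    @property
    def transflectance(self) -> float:
        return 1.0 - self.absorbed


@dataclass(frozen=True)
class PatternProfile:
    """Surface exit profile along x for one sinusoidal illumination phase.

    ``profile`` is normalized to the mean illumination intensity, so in
    expectation it equals ``R_DC + R_AC * cos(2 pi fx x + phase)``.
    ``sum_w``/``sum_w2`` are raw top-escape weight tallies for error
    estimation.
    """

    x: np.ndarray
    profile: np.ndarray
    fx: float
    phase: float
    n_photons: int
    sum_w: float
    sum_w2: float


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _xorshift128p(s0, s1):
    """One step of xorshift128+; returns (uniform in [0,1), new s0, new s1)."""
    x = s0
    y = s1
    s0 = y
    x ^= x << np.uint64(23)
    x ^= x >> np.uint64(17)
    x ^= y ^ (y >> np.uint64(26))
    s1 = x
    u = np.float64((x + y) >> np.uint64(11)) * (1.0 / 9007199254740992.0)
    return u, s0, s1


@njit(cache=True, fastmath=True, inline="always")
def _icdf_draw(icdf, delta_c, u):
    pos = u / delta_c - 1.0
    if pos <= 0.0:
        return icdf[0]
    i = int(pos)
    if i >= icdf.shape[0] - 1:
        return icdf[icdf.shape[0] - 1]
    f = pos - i
    return icdf[i] * (1.0 - f) + icdf[i + 1] * f


@njit(cache=True, fastmath=True, inline="always")
def _fresnel_reflectance(n_i, n_t, cos_i):
    n_rel = n_i / n_t
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _transport_kernel(
    seed,
    n_photons,
    mua,
    mus,
    n_in,
    n_out,
    v,
    t_max,
    icdf,
    delta_c,
    thickness,
    cyclic,
    period_x,
    period_y,
    src_mode,
    fx,
    phase,
    beam_radius,
    w_cutoff,
):
    s0 = _splitmix64(np.uint64(seed))
    s1 = _splitmix64(np.uint64(seed) + np.uint64(0x5851F42D4C957F2D))
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(1)
    out_x = np.empty(n_photons)
    out_y = np.empty(n_photons)
    out_t = np.empty(n_photons)
    out_w = np.empty(n_photons)
    out_side = np.empty(n_photons, dtype=np.int8)
    absorbed = 0.0
    l_max = t_max * v
    spec_r = 0.0
    if n_in != n_out:
        spec_r = ((n_in - n_out) / (n_in + n_out)) ** 2

    for ip in range(n_photons):
        # --- launch ---
        if src_mode == _SRC_PATTERN:
            while True:
                u, s0, s1 = _xorshift128p(s0, s1)
                x = u * period_x
                u, s0, s1 = _xorshift128p(s0, s1)
                if u <= 0.5 * (1.0 + np.cos(2.0 * np.pi * fx * x + phase)):
                    break
            u, s0, s1 = _xorshift128p(s0, s1)
            y = u * period_y
        elif src_mode == _SRC_DISC:
            while True:
                u, s0, s1 = _xorshift128p(s0, s1)
                x = (2.0 * u - 1.0) * beam_radius
                u, s0, s1 = _xorshift128p(s0, s1)
                y = (2.0 * u - 1.0) * beam_radius
                if x * x + y * y <= beam_radius * beam_radius:
                    break
        else:
            x = 0.0
            y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        path = 0.0  # total pathlength, mm

        if spec_r > 0.0:
            u, s0, s1 = _xorshift128p(s0, s1)
            if u < spec_r:
                out_x[ip] = x
                out_y[ip] = y
                out_t[ip] = 0.0
                out_w[ip] = w
                out_side[ip] = SIDE_SPECULAR
                continue

        if mus > 0.0:
            u, s0, s1 = _xorshift128p(s0, s1)
            step = -np.log(1.0 - u) / mus
        else:
            step = 1e30
        side = -1
        while True:
            # distance to the nearest z boundary along the current direction
            if uz > 0.0:
                d_bound = (thickness - z) / uz
            elif uz < 0.0:
                d_bound = -z / uz
            else:
                d_bound = 1e30

            hop = step if step < d_bound else d_bound
            # time cap applies mid-hop
            capped = False
            if path + hop > l_max:
                hop = l_max - path
                capped = True

            x += ux * hop
            y += uy * hop
            z += uz * hop
            path += hop
            if cyclic:
                x = x % period_x
                y = y % period_y
            if mua > 0.0:
                decay = np.exp(-mua * hop)
                absorbed += w * (1.0 - decay)
                w *= decay

            if capped:
                side = SIDE_TIME_CAP
                break

            if hop == d_bound and step >= d_bound:
                # boundary interaction
                cos_i = uz if uz > 0.0 else -uz
                refl = _fresnel_reflectance(n_in, n_out, cos_i)
                u, s0, s1 = _xorshift128p(s0, s1)
                if refl > 0.0 and u < refl:
                    uz = -uz
                    step -= d_bound
                    if step <= 0.0:
                        step = 1e-12
                    # clamp to the boundary plane to avoid drift
                    if z < 0.0:
                        z = 0.0
                    elif z > thickness:
                        z = thickness
                    continue
                side = SIDE_TOP if uz < 0.0 else SIDE_BOTTOM
                break

            # scattering event
            u, s0, s1 = _xorshift128p(s0, s1)
            step = -np.log(1.0 - u) / mus
            u, s0, s1 = _xorshift128p(s0, s1)
            cost = _icdf_draw(icdf, delta_c, u)
            sint = np.sqrt(max(0.0, 1.0 - cost * cost))
            # uniform azimuth without trig: Marsaglia polar rejection
            while True:
                u, s0, s1 = _xorshift128p(s0, s1)
                a = 2.0 * u - 1.0
                u, s0, s1 = _xorshift128p(s0, s1)
                b = 2.0 * u - 1.0
                norm2 = a * a + b * b
                if 0.0 < norm2 <= 1.0:
                    break
            cosp = (a * a - b * b) / norm2
            sinp = 2.0 * a * b / norm2
            if uz > 0.99999 or uz < -0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                nuz = -den * sint * cosp + uz * cost
                norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm

            if w < w_cutoff:
                absorbed += w
                w = 0.0
                side = SIDE_WEIGHT_CUT
                break

        out_x[ip] = x
        out_y[ip] = y
        out_t[ip] = path / v
        out_w[ip] = w
        out_side[ip] = side
    return out_x, out_y, out_t, out_w, out_side, absorbed


def _run(config: TransportConfig, thickness, cyclic, period_x, period_y,
         src_mode, fx=0.0, phase=0.0, beam_radius=0.0) -> ExitRecords:
    icdf = np.ascontiguousarray(config.spf.cos_theta, dtype=np.float64)
    x, y, t, w, side, absorbed = _transport_kernel(
        config.seed,
        config.n_photons,
        config.mua,
        config.mus,
        config.n_medium,
        config.n_outside,
        config.speed,
        config.t_max,
        icdf,
        config.spf.delta_c,
        thickness,
        cyclic,
        period_x,
        period_y,
        src_mode,
        fx,
        phase,
        beam_radius,
        config.weight_cutoff,
    )
    return ExitRecords(
        x=x,
        y=y,
        time_of_flight=t,
        weight=w,
        side=side,
        absorbed=absorbed,
        n_launched=config.n_photons,
        config=config,
    )


def propagate_pencil(config: TransportConfig) -> ExitRecords:
    """Pencil beam on a semi-infinite half-space; white-MC source geometry.

    Photons launch normally at the origin and are tracked until they escape
    through the top surface or exceed the time cap.  The returned records
    carry one entry per launched photon; use :meth:`ExitRecords.escaped_top`
    for the remitted set feeding the white-MC histogram.
    """
    return _run(config, thickness=1e12, cyclic=False, period_x=0.0,
                period_y=0.0, src_mode=_SRC_PENCIL)


def simulate_slab(
    config: TransportConfig,
    thickness: float,
    beam_diameter: float = 1.0,
    lateral_period: float = 2.0,
) -> SlabResult:
    """Finite slab with cyclic lateral boundaries: R, T, A energy split.

    A uniform disc beam is incident on a slab of the given thickness (mm);
    lateral faces are cyclic so the slab behaves as laterally infinite.
    Returns the fractions of launched weight reflected (specular included),
    transmitted, and absorbed; ``R + T + A + dropped = 1`` exactly.
    """
    if thickness <= 0.0:
        raise ValueError("thickness must be positive")
    rec = _run(
        config,
        thickness=thickness,
        cyclic=True,
        period_x=lateral_period,
        period_y=lateral_period,
        src_mode=_SRC_DISC,
        beam_radius=beam_diameter / 2.0,
    )
    led = rec.ledger()
    return SlabResult(
        reflectance=led["top"] + led["specular"],
        transmittance=led["bottom"],
        absorbed=led["absorbed"],
        dropped=led["time_cap"],
        specular=led["specular"],
    )


def penetration_depth(mua: float, mus_prime: float, fx: float) -> float:
    """Effective SFD penetration depth ``1/sqrt(3 mua (mua + mus') + (2 pi fx)^2)``."""
    return 1.0 / np.sqrt(3.0 * mua * (mua + mus_prime) + (2.0 * np.pi * fx) ** 2)


def simulate_sfdi_pattern(
    config: TransportConfig,
    fx: float,
    phase: float,
    bins_per_period: int = 25,
    n_periods: int = 2,
    depth_factor: float = 5.0,
    width: float = 1.0,
) -> PatternProfile:
    """Direct simulation of sinusoidally patterned illumination.

    Launch positions are drawn from ``0.5 (1 + cos(2 pi fx x + phase))``
    over ``n_periods`` periods; the domain is cyclic laterally and extends
    ``depth_factor`` penetration depths deep (the bottom face absorbs).
    The exit profile is binned along x (``bins_per_period`` bins per
    period) and normalized to the mean illumination intensity, so that
    three-phase demodulation of such profiles recovers the DC and AC
    diffuse reflectance directly.
    """
    if fx <= 0.0:
        raise ValueError("fx must be positive for a patterned source")
    # depth by the DC (fx=0) penetration depth when absorbing: the diffuse DC
    # component penetrates deeper than the AC pattern, and a domain sized to
    # the fx-dependent depth truncates it measurably at low fx
    fx_depth = 0.0 if config.mua > 0.0 else fx
    depth = depth_factor * penetration_depth(config.mua, config.mus_prime, fx_depth)
    length = n_periods / fx
    rec = _run(
        config,
        thickness=depth,
        cyclic=True,
        period_x=length,
        period_y=width,
        src_mode=_SRC_PATTERN,
        fx=fx,
        phase=phase,
    )
    top = rec.side == SIDE_TOP
    nbins = bins_per_period * n_periods
    edges = np.linspace(0.0, length, nbins + 1)
    hist, _ = np.histogram(rec.x[top], bins=edges, weights=rec.weight[top])
    # counts/(N dx) is exit weight per unit length; multiplying by the domain
    # length converts to reflectance relative to the mean illumination
    profile = hist * nbins / rec.n_launched
    centers = 0.5 * (edges[:-1] + edges[1:])
    w_top = rec.weight[top]
    return PatternProfile(
        x=centers,
        profile=profile,
        fx=fx,
        phase=phase,
        n_photons=rec.n_launched,
        sum_w=float(w_top.sum()),
        sum_w2=float((w_top**2).sum()),
    )


def demod_three_phase(p0, p1, p2, fx: float = 0.0) -> ReflectancePair:
    """Three-phase demodulation of aligned reflectance profiles.

    ``AC = (sqrt(2)/3) sqrt((P0-P1)^2 + (P1-P2)^2 + (P2-P0)^2)`` evaluated
    pointwise and averaged over space; ``DC`` is the mean of the three
    profiles.  Exact for noiseless sinusoids at phases 0, 2pi/3, 4pi/3.
    """
    a0, a1, a2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    if not (a0.shape == a1.shape == a2.shape):
        raise ValueError("profiles must have identical shapes")
    ac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (a0 - a1) ** 2 + (a1 - a2) ** 2 + (a2 - a0) ** 2
    )
    dc = (a0 + a1 + a2) / 3.0
    return ReflectancePair(dc=float(dc.mean()), ac=float(ac.mean()), fx=fx)
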