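"""White Monte Carlo forward model and lookup-table construction.

A white Monte Carlo (wMC) record is a bivariate histogram of remitted
photon weight over exit radius and time of flight, computed once for a
pencil beam on an effectively non-absorbing half-space at a base reduced
scattering coefficient (10 mm^-1 here).  Reflectance at arbitrary optical
properties follows without re-simulation:

* scaling ``mus'`` by ``beta`` rescales both the radial and temporal bin
  coordinates by ``1/beta`` (similarity of the scattering random walk at
  fixed reduced scattering);
* absorption multiplies each time bin by the Beer-Lambert factor
  ``exp(-mua * (c/n) * t_scaled)``.

Summing over time yields the spatially resolved diffuse reflectance
``R(rho)``; an order-zero Hankel transform converts it to the
spatial-frequency-dependent reflectance ``Rd(fx)`` used by SFDI.  Both bin
axes are logarithmically spaced (750 bins from 1e-5 to 150 mm and 1e-7 to
300 ns) so that sub-diffuse structure picoseconds and micrometres from the
source coexists with the full diffuse tail in a single compact array.

Inversion LUTs map a (DC, AC) reflectance pair at one spatial frequency
back to ``(mua, mus')`` by inverting the dense forward surface onto fixed
log-spaced reflectance grids; unreachable or non-invertible nodes are
flagged rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator, griddata
from scipy.special import j0

from sfdimc.phase_functions import InverseCdfTable
from sfdimc.transport import (
    C_MM_PER_NS,
    ExitRecords,
    ReflectancePair,
    TransportConfig,
    propagate_pencil,
)

__all__ = [
    "BinSpec",
    "WhiteMCRecord",
    "RadialReflectance",
    "InversionLUT",
    "bin_records",
    "build_white_mc",
    "apply_props",
    "hankel_rd",
    "predict_pair",
    "predict_pair_with_se",
    "build_lut",
]

BASE_MUS_PRIME = 10.0  # mm^-1, reduced scattering of the base pencil run
BASE_MUA = 1e-8  # mm^-1, effectively non-absorbing


def _log_centers(lo: float, hi: float, n: int) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def _edges_from_centers(centers: np.ndarray) -> np.ndarray:
    """Edges at geometric midpoints; end edges extend by the common ratio."""
    ratio = centers[1] / centers[0]
    inner = np.sqrt(centers[:-1] * centers[1:])
    return np.concatenate(
        [[centers[0] / np.sqrt(ratio)], inner, [centers[-1] * np.sqrt(ratio)]]
    )


@dataclass(frozen=True)
class BinSpec:
    """Log-spaced bin configuration for the white-MC histogram."""

    r_min: float = 1e-5
    r_max: float = 150.0
    t_min: float = 1e-7
    t_max: float = 300.0
    n_bins: int = 750

    def r_centers(self) -> np.ndarray:
        return _log_centers(self.r_min, self.r_max, self.n_bins)

    def t_centers(self) -> np.ndarray:
        return _log_centers(self.t_min, self.t_max, self.n_bins)


@dataclass
class WhiteMCRecord:
    """Log-binned 2D histogram (radius x time) of remitted photon weight.

    The forward-model kernel: all reflectance predictions derive from this
    array by coordinate scaling and Beer-Lambert weighting.  ``counts``
    holds escaped weight per (radius bin, time bin); ``out_of_range`` is
    the escaped weight falling outside the binned domain (guard tally,
    excluded from transforms).
    """

    counts: np.ndarray
    r_centers: np.ndarray
    t_centers: np.ndarray
    n_launched: int
    base_mus_prime: float = BASE_MUS_PRIME
    base_mua: float = BASE_MUA
    n_medium: float = 1.56
    out_of_range: float = 0.0
    spf_label: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.t_centers = np.asarray(self.t_centers, dtype=float)
        if self.counts.shape != (self.r_centers.size, self.t_centers.size):
            raise ValueError("counts shape must be (n_radius_bins, n_time_bins)")
        if np.any(self.counts < 0.0):
            raise ValueError("histogram counts must be non-negative")
        for centers in (self.r_centers, self.t_centers):
            ratios = centers[1:] / centers[:-1]
            if np.any(np.diff(centers) <= 0) or not np.allclose(
                ratios, ratios[0], rtol=1e-8
            ):
                raise ValueError("bin centers must be strictly increasing and log-spaced")

    @property
    def speed(self) -> float:
        return C_MM_PER_NS / self.n_medium

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts, compression="gzip")
            f.create_dataset("r_centers", data=self.r_centers)
            f.create_dataset("t_centers", data=self.t_centers)
            f.attrs.update(
                {
                    "n_launched": self.n_launched,
                    "base_mus_prime": self.base_mus_prime,
                    "base_mua": self.base_mua,
                    "n_medium": self.n_medium,
                    "out_of_range": self.out_of_range,
                    "spf_label": self.spf_label,
                    "seed": -1 if self.seed is None else self.seed,
                }
            )

    @classmethod
    def from_hdf5(cls, path) -> "WhiteMCRecord":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            return cls(
                counts=f["counts"][...],
                r_centers=f["r_centers"][...],
                t_centers=f["t_centers"][...],
                n_launched=int(f.attrs["n_launched"]),
                base_mus_prime=float(f.attrs["base_mus_prime"]),
                base_mua=float(f.attrs["base_mua"]),
                n_medium=float(f.attrs["n_medium"]),
                out_of_range=float(f.attrs["out_of_range"]),
                spf_label=str(f.attrs["spf_label"]),
                seed=None if seed < 0 else seed,
            )


@dataclass(frozen=True)
class RadialReflectance:
    """Spatially resolved diffuse reflectance on the (scaled) radial grid.

    ``rd_per_area`` is per-photon reflectance per unit area (mm^-2);
    ``weight_fraction`` is the per-annulus escaped fraction
    (``rd_per_area * annulus area``), the natural quadrature weight for the
    Hankel transform on the log grid.
    """

    rho: np.ndarray
    rd_per_area: np.ndarray
    weight_fraction: np.ndarray
    annulus_area: np.ndarray

    @property
    def total(self) -> float:
        """Plane-integrated diffuse reflectance."""
        return float(self.weight_fraction.sum())


def bin_records(records: ExitRecords, spec: BinSpec = BinSpec()) -> WhiteMCRecord:
    """Histogram top-escaping photons into the log-spaced (radius, time) grid.

    Total binned weight plus the out-of-range tally equals the total escaped
    weight exactly.
    """
    top = records.escaped_top()
    r_centers = spec.r_centers()
    t_centers = spec.t_centers()
    r_edges = _edges_from_centers(r_centers)
    t_edges = _edges_from_centers(t_centers)
    counts, _, _ = np.histogram2d(
        top.radius, top.time_of_flight, bins=[r_edges, t_edges], weights=top.weight
    )
    escaped = float(top.weight.sum())
    cfg = records.config
    return WhiteMCRecord(
        counts=counts,
        r_centers=r_centers,
        t_centers=t_centers,
        n_launched=records.n_launched,
        base_mus_prime=cfg.mus_prime if cfg.g1 is not None else BASE_MUS_PRIME,
        base_mua=cfg.mua,
        n_medium=cfg.n_medium,
        out_of_range=escaped - float(counts.sum()),
        spf_label=cfg.spf.label,
        seed=cfg.seed,
    )


def build_white_mc(
    spf: InverseCdfTable,
    g1: float,
    n_photons: int = 1_000_000,
    seed: int = 0,
    t_max: float = 300.0,
    n_medium: float = 1.56,
    spec: BinSpec = BinSpec(),
) -> WhiteMCRecord:
    """Run the base pencil simulation and bin it into a white-MC record.

    The base medium has ``mua = 1e-8 mm^-1``, ``mus' = 10 mm^-1`` and the
    given refractive index against air.
    """
    config = TransportConfig.from_reduced(
        mua=BASE_MUA,
        mus_prime=BASE_MUS_PRIME,
        g1=g1,
        spf=spf,
        n_medium=n_medium,
        n_outside=1.0,
        t_max=t_max,
        n_photons=n_photons,
        seed=seed,
    )
    return bin_records(propagate_pencil(config), spec)


def apply_props(wmc: WhiteMCRecord, mua: float, mus_prime: float) -> RadialReflectance:
    """Rescale the record to ``(mua, mus')`` and collapse over time.

    ``beta = mus'/base_mus'`` rescales bin coordinates by ``1/beta``; each
    cell is weighted by ``exp(-mua (c/n) t_scaled)`` and summed over time;
    the radial profile is divided by the scaled annulus areas and the
    launched photon count.
    """
    if mus_prime <= 0.0:
        raise ValueError("mus_prime must be positive")
    if mua < 0.0:
        raise ValueError("mua must be non-negative")
    beta = mus_prime / wmc.base_mus_prime
    rho = wmc.r_centers / beta
    t_scaled = wmc.t_centers / beta
    decay = np.exp(-mua * wmc.speed * t_scaled)
    weight_r = wmc.counts @ decay
    edges = _edges_from_centers(wmc.r_centers) / beta
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    frac = weight_r / wmc.n_launched
    return RadialReflectance(
        rho=rho, rd_per_area=frac / areas, weight_fraction=frac, annulus_area=areas
    )


def hankel_rd(profile: RadialReflectance, fx: float) -> float:
    """Order-zero Hankel transform of the radial profile at frequency ``fx``.

    ``Rd(fx) = 2 pi sum rd(rho_i) J0(2 pi fx rho_i) rho_i drho_i`` with
    midpoint quadrature on the log-spaced annuli, i.e. the per-annulus
    escaped fraction weighted by ``J0``.  ``Rd(0)`` is the total diffuse
    reflectance.
    """
    if fx < 0.0:
        raise ValueError("fx must be non-negative")
    if fx == 0.0:
        return profile.total
    return float(np.sum(profile.weight_fraction * j0(2.0 * np.pi * fx * profile.rho)))


def predict_pair(
    wmc: WhiteMCRecord, mua: float, mus_prime: float, fx: float
) -> ReflectancePair:
    """(DC, AC) reflectance pair at the given properties and frequency."""
    prof = apply_props(wmc, mua, mus_prime)
    return ReflectancePair(dc=hankel_rd(prof, 0.0), ac=hankel_rd(prof, fx), fx=fx)


def predict_pair_with_se(
    wmc: WhiteMCRecord, mua: float, mus_prime: float, fx: float
):
    """Reflectance pair plus Monte Carlo standard errors.

    Treats each binned photon as an independent draw of the per-photon
    estimator ``J0(2 pi fx r) exp(-mua v t)`` (unit weights, as in the
    near-lossless base run); the standard error is the sample standard
    deviation over launched photons divided by ``sqrt(n)``.
    """
    beta = mus_prime / wmc.base_mus_prime
    rho = wmc.r_centers / beta
    decay = np.exp(-mua * wmc.speed * wmc.t_centers / beta)
    n = wmc.n_launched
    out = {}
    for key, fq in (("dc", 0.0), ("ac", fx)):
        bessel = np.ones_like(rho) if fq == 0.0 else j0(2.0 * np.pi * fq * rho)
        vals = bessel[:, None] * decay[None, :]
        mean = float(np.sum(wmc.counts * vals)) / n
        second = float(np.sum(wmc.counts * vals**2)) / n
        out[key] = (mean, np.sqrt(max(second - mean**2, 0.0) / n))
    pair = ReflectancePair(dc=out["dc"][0], ac=out["ac"][0], fx=fx)
    return pair, {"dc": out["dc"][1], "ac": out["ac"][1]}


@dataclass
class InversionLUT:
    """Lookup table mapping (DC, AC) reflectance to ``(mua, mus')``.

    Reflectance axes are log-spaced (DC: 0.001-0.9 over 190 points, AC:
    0.001-0.7 over 170 points).  Surface nodes with no physical solution
    (outside the forward surface, AC >= DC, or failing the forward
    consistency check) hold NaN and are reported as undetermined on lookup.
    """

    dc_grid: np.ndarray
    ac_grid: np.ndarray
    mua_surface: np.ndarray
    mus_prime_surface: np.ndarray
    fx: float
    spf_label: str = ""

    def __post_init__(self) -> None:
        if self.mua_surface.shape != (self.dc_grid.size, self.ac_grid.size):
            raise ValueError("surface shape must be (len(dc_grid), len(ac_grid))")
        if np.any(np.diff(self.dc_grid) <= 0) or np.any(np.diff(self.ac_grid) <= 0):
            raise ValueError("reflectance grids must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.mua_surface < 0) or np.any(self.mus_prime_surface <= 0):
                raise ValueError("property surfaces must be positive where defined")

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of nodes with no physical solution."""
        return ~np.isfinite(self.mua_surface) | ~np.isfinite(self.mus_prime_surface)

    def lookup(self, dc, ac):
        """Bilinear interpolation in log-reflectance coordinates.

        Returns ``(mua, mus_prime, undetermined)`` arrays broadcast to the
        input shape.  A query is undetermined when AC >= DC, either value
        falls off the grid, or the interpolation touches a flagged node.
        """
        dc = np.asarray(dc, dtype=float)
        ac = np.asarray(ac, dtype=float)
        pts = np.stack(
            [
                np.log(np.clip(dc, 1e-300, None)),
                np.log(np.clip(ac, 1e-300, None)),
            ],
            axis=-1,
        )
        interp_a = RegularGridInterpolator(
            (np.log(self.dc_grid), np.log(self.ac_grid)),
            self.mua_surface,
            bounds_error=False,
            fill_value=np.nan,
        )
        interp_s = RegularGridInterpolator(
            (np.log(self.dc_grid), np.log(self.ac_grid)),
            self.mus_prime_surface,
            bounds_error=False,
            fill_value=np.nan,
        )
        mua = interp_a(pts).reshape(dc.shape)
        mus = interp_s(pts).reshape(dc.shape)
        undet = ~np.isfinite(mua) | ~np.isfinite(mus) | (ac >= dc) | (dc <= 0) | (ac <= 0)
        return mua, mus, undet

    def to_csv(self) -> str:
        """Flat CSV export of the grids and property surfaces."""
        lines = [f"# fx = {self.fx}", f"# spf = {self.spf_label}", "dc,ac,mua,mus_prime"]
        for i, d in enumerate(self.dc_grid):
            for k, a in enumerate(self.ac_grid):
                lines.append(
                    f"{d:.8g},{a:.8g},{self.mua_surface[i, k]:.8g},"
                    f"{self.mus_prime_surface[i, k]:.8g}"
                )
        return "\n".join(lines) + "\n"

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("dc_grid", "ac_grid", "mua_surface", "mus_prime_surface"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["fx"] = self.fx
            f.attrs["spf_label"] = self.spf_label

    @classmethod
    def from_hdf5(cls, path) -> "InversionLUT":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                dc_grid=f["dc_grid"][...],
                ac_grid=f["ac_grid"][...],
                mua_surface=f["mua_surface"][...],
                mus_prime_surface=f["mus_prime_surface"][...],
                fx=float(f.attrs["fx"]),
                spf_label=str(f.attrs["spf_label"]),
            )


def _forward_surfaces(wmc, fx, mua_vals, mus_vals):
    """Dense forward model: (mua, mus') grids -> (DC, AC) arrays."""
    n = wmc.n_launched
    v = wmc.speed
    dc = np.empty((mua_vals.size, mus_vals.size))
    ac = np.empty_like(dc)
    for k, mus_p in enumerate(mus_vals):
        beta = mus_p / wmc.base_mus_prime
        rho = wmc.r_centers / beta
        bessel = j0(2.0 * np.pi * fx * rho)
        decay = np.exp(-np.outer(v * wmc.t_centers / beta, mua_vals))  # (t, mua)
        weight = wmc.counts @ decay  # (r, mua)
        dc[:, k] = weight.sum(axis=0) / n
        ac[:, k] = bessel @ weight / n
    return dc, ac


def build_lut(
    wmc: WhiteMCRecord,
    fx: float,
    n_dc: int = 190,
    n_ac: int = 170,
    dc_range: tuple = (0.001, 0.9),
    ac_range: tuple = (0.001, 0.7),
    n_mua: int = 120,
    n_mus: int = 120,
    mua_range: tuple = (1e-4, 10.0),
    mus_range: tuple = (0.1, 10.0),
    consistency_rtol: float = 0.05,
) -> InversionLUT:
    """Invert the forward surface onto fixed log-spaced reflectance grids.

    The forward pair (DC, AC) is computed on a dense log-spaced property
    grid, triangulated in log-reflectance space, and linearly interpolated
    onto the LUT grids.  Nodes outside the forward surface, with
    ``AC >= DC``, or whose inverted properties fail to reproduce the node
    reflectance within ``consistency_rtol`` (the fold at high absorption)
    are flagged NaN.
    """
    mua_vals = np.geomspace(*mua_range, n_mua)
    mus_vals = np.geomspace(*mus_range, n_mus)
    dc_fwd, ac_fwd = _forward_surfaces(wmc, fx, mua_vals, mus_vals)

    dc_grid = np.geomspace(*dc_range, n_dc)
    ac_grid = np.geomspace(*ac_range, n_ac)

    # drop forward points with non-positive reflectance (deep-absorption
    # corner where Monte Carlo noise dominates a vanishing signal)
    good = (dc_fwd.ravel() > 0.0) & (ac_fwd.ravel() > 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pts = np.column_stack(
            [np.log(dc_fwd.ravel()[good]), np.log(ac_fwd.ravel()[good])]
        )
    log_mua = np.log(np.broadcast_to(mua_vals[:, None], dc_fwd.shape).ravel()[good])
    log_mus = np.log(np.broadcast_to(mus_vals[None, :], dc_fwd.shape).ravel()[good])

    qd, qa = np.meshgrid(np.log(dc_grid), np.log(ac_grid), indexing="ij")
    query = np.column_stack([qd.ravel(), qa.ravel()])
    mua_surf = np.exp(griddata(pts, log_mua, query, method="linear")).reshape(
        n_dc, n_ac
    )
    mus_surf = np.exp(griddata(pts, log_mus, query, method="linear")).reshape(
        n_dc, n_ac
    )

    unphysical = dc_grid[:, None] <= ac_grid[None, :]
    mua_surf[unphysical] = np.nan
    mus_surf[unphysical] = np.nan

    # forward-consistency check: push the inverted properties back through a
    # bilinear surrogate of the forward surface and require the node pair back
    with np.errstate(invalid="ignore", divide="ignore"):
        log_dc_fwd = np.where(dc_fwd > 0.0, np.log(np.abs(dc_fwd) + 1e-300), np.nan)
        log_ac_fwd = np.where(ac_fwd > 0.0, np.log(np.abs(ac_fwd) + 1e-300), np.nan)
    fwd_dc = RegularGridInterpolator(
        (np.log(mua_vals), np.log(mus_vals)), log_dc_fwd,
        bounds_error=False, fill_value=np.nan,
    )
    fwd_ac = RegularGridInterpolator(
        (np.log(mua_vals), np.log(mus_vals)), log_ac_fwd,
        bounds_error=False, fill_value=np.nan,
    )
    ok = np.isfinite(mua_surf) & np.isfinite(mus_surf)
    if np.any(ok):
        p = np.column_stack([np.log(mua_surf[ok]), np.log(mus_surf[ok])])
        dc_back = np.exp(fwd_dc(p))
        ac_back = np.exp(fwd_ac(p))
        node_dc = np.broadcast_to(dc_grid[:, None], mua_surf.shape)[ok]
        node_ac = np.broadcast_to(ac_grid[None, :], mua_surf.shape)[ok]
        bad = (
            ~np.isfinite(dc_back)
            | ~np.isfinite(ac_back)
            | (np.abs(dc_back - node_dc) > consistency_rtol * node_dc)
            | (np.abs(ac_back - node_ac) > consistency_rtol * node_ac)
        )
        idx = np.where(ok)
        mua_surf[idx[0][bad], idx[1][bad]] = np.nan
        mus_surf[idx[0][bad], idx[1][bad]] = np.nan

    return InversionLUT(
        dc_grid=dc_grid,
        ac_grid=ac_grid,
        mua_surface=mua_surf,
        mus_prime_surface=mus_surf,
        fx=fx,
        spf_label=wmc.spf_label,
    )
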