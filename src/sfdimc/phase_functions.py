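"""Single- and two-term Henyey-Greenstein scattering phase functions.

The scattering phase function (SPF) gives the probability density, per unit
solid angle, of a photon being deflected by an angle ``theta`` in a single
scattering event.  The single-term Henyey-Greenstein function (stHG) is the
workhorse of tissue optics; the two-term variant (ttHG) adds a weighted
backward lobe so that materials with a distinct backscatter component (such
as zinc oxide powders) can be represented:

    p(cos t) = (1/4pi) * [ alpha * K(gf, cos t) + (1 - alpha) * K(gb, cos t) ]

with ``K(g, x) = (1 - g^2) / (1 + g^2 - 2 g x)^{3/2}`` and the overall
anisotropy ``g1 = <cos t> = alpha*gf + (1 - alpha)*gb``.

Monte Carlo transport samples the deflection cosine through a numerically
tabulated inverse cumulative distribution function, built once per SPF and
evaluated by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SthgParams",
    "TtHGParams",
    "InverseCdfTable",
    "eval_sthg",
    "eval_tthg",
    "mean_cosine",
    "build_inverse_cdf",
    "sample_cos_theta",
    "sthg_inverse_cdf",
]

_FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class SthgParams:
    """Single-term Henyey-Greenstein anisotropy, ``|g| < 1``."""

    g: float

    def __post_init__(self) -> None:
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"stHG anisotropy must satisfy |g| < 1, got {self.g}")


@dataclass(frozen=True)
class TtHGParams:
    """Two-term Henyey-Greenstein parameters.

    Parameters
    ----------
    alpha : float
        Fractional contribution of the forward lobe, in ``[0, 1]``.
    gf : float
        Forward anisotropy, in ``[0, 1)``.
    gb : float
        Backward anisotropy, in ``(-1, 0]``.
    """

    alpha: float
    gf: float
    gb: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gf < 1.0:
            raise ValueError(f"gf must lie in [0, 1), got {self.gf}")
        if not -1.0 < self.gb <= 0.0:
            raise ValueError(f"gb must lie in (-1, 0], got {self.gb}")

    @property
    def g1(self) -> float:
        """Overall anisotropy ``<cos t> = alpha*gf + (1-alpha)*gb``."""
        return self.alpha * self.gf + (1.0 - self.alpha) * self.gb


def _hg_kernel(g: float, cos_theta: np.ndarray) -> np.ndarray:
    return (1.0 - g * g) / (1.0 + g * g - 2.0 * g * cos_theta) ** 1.5


def _check_cos(cos_theta) -> np.ndarray:
    x = np.asarray(cos_theta, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("cos_theta must lie in [-1, 1]")
    return np.clip(x, -1.0, 1.0)


def eval_sthg(params: SthgParams, cos_theta):
    """stHG density per steradian, ``(1/4pi)(1-g^2)/(1+g^2-2g cos t)^{3/2}``."""
    x = _check_cos(cos_theta)
    return _hg_kernel(params.g, x) / _FOUR_PI


def eval_tthg(params: TtHGParams, cos_theta):
    """ttHG density per steradian: weighted sum of forward and backward stHG lobes."""
    x = _check_cos(cos_theta)
    fwd = _hg_kernel(params.gf, x)
    bwd = _hg_kernel(params.gb, x)
    return (params.alpha * fwd + (1.0 - params.alpha) * bwd) / _FOUR_PI


def mean_cosine(params) -> float:
    """Anisotropy ``g1`` of an stHG or ttHG phase function (closed form)."""
    if isinstance(params, SthgParams):
        return params.g
    if isinstance(params, TtHGParams):
        return params.g1
    raise TypeError(f"unsupported phase-function parameters: {params!r}")


@dataclass(frozen=True)
class InverseCdfTable:
    """Tabulated inverse CDF of a phase function over the deflection cosine.

    ``cos_theta[i]`` is the deflection cosine whose CDF equals ``grid[i]``,
    where ``grid`` is the regular ladder ``delta_c, 2*delta_c, ..., 1-delta_c``.
    Sampling draws a uniform variate and interpolates linearly; values below
    ``delta_c`` or above ``1-delta_c`` clamp to the table ends.
    """

    grid: np.ndarray
    cos_theta: np.ndarray
    delta_c: float
    label: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        cos = np.asarray(self.cos_theta, dtype=float)
        if grid.shape != cos.shape or grid.ndim != 1:
            raise ValueError("grid and cos_theta must be matching 1-D arrays")
        steps = np.diff(grid)
        if not np.allclose(steps, self.delta_c, rtol=1e-6, atol=1e-12):
            raise ValueError("grid step does not equal the configured delta_c")
        if np.any(np.diff(cos) < -1e-12):
            raise ValueError("cos_theta must be non-decreasing along the grid")
        if cos[0] < -1.0 - 1e-9 or cos[-1] > 1.0 + 1e-9:
            raise ValueError("cos_theta endpoints must lie within [-1, 1]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "cos_theta", np.clip(cos, -1.0, 1.0))

    def to_table(self) -> np.ndarray:
        """Two-column (CDF, cos_theta) array for plain-text serialization."""
        return np.column_stack([self.grid, self.cos_theta])

    @classmethod
    def from_table(cls, arr: np.ndarray, label: str = "") -> "InverseCdfTable":
        arr = np.asarray(arr, dtype=float)
        delta_c = float(arr[0, 0])
        return cls(grid=arr[:, 0], cos_theta=arr[:, 1], delta_c=delta_c, label=label)


def build_inverse_cdf(
    spf: Callable[[np.ndarray], np.ndarray],
    delta_c: float = 1e-4,
    cos_step: float = 1e-4,
    label: str = "",
) -> InverseCdfTable:
    """Tabulate the inverse CDF of an arbitrary phase-function density.

    The density ``spf(cos_theta)`` (per steradian) is integrated over solid
    angle on a regular cosine grid of step ``cos_step`` from -1 to 1, using
    5-point Gauss-Legendre quadrature within each cell (a strongly forward
    HG lobe, e.g. ``g = 0.98``, varies too sharply across the final cells
    for the trapezoid rule to place its mass correctly); the (CDF, cos)
    relation is then flipped and interpolated onto the linear CDF ladder
    ``delta_c : delta_c : 1-delta_c``.

    Raises
    ------
    ValueError
        If the density is negative, non-finite, or does not integrate to 1
        over the sphere to within 1 percent (non-normalizable).
    """
    if not 0.0 < delta_c <= 0.1:
        raise ValueError(f"delta_c must lie in (0, 0.1], got {delta_c}")
    n = int(round(2.0 / cos_step)) + 1
    cos_grid = np.linspace(-1.0, 1.0, n)
    # per-cell Gauss-Legendre nodes and weights on [-1, 1]
    gl_x, gl_w = np.polynomial.legendre.leggauss(5)
    half = 0.5 * np.diff(cos_grid)  # (n-1,)
    mid = 0.5 * (cos_grid[:-1] + cos_grid[1:])
    nodes = mid[:, None] + half[:, None] * gl_x[None, :]
    dens = np.asarray(spf(nodes.ravel()), dtype=float).reshape(nodes.shape)
    if np.any(~np.isfinite(dens)) or np.any(dens < 0.0):
        raise ValueError("phase-function density must be finite and non-negative")
    # CDF over solid angle: 2*pi * int p(x) dx
    increments = (dens * gl_w[None, :]).sum(axis=1) * half
    cdf = np.concatenate([[0.0], np.cumsum(increments)]) * 2.0 * np.pi
    total = cdf[-1]
    if not np.isfinite(total) or total <= 0.0 or abs(total - 1.0) > 1e-2:
        raise ValueError(
            f"density integrates to {total:.6g} over the sphere; not a normalized SPF"
        )
    cdf = cdf / total
    m = int(round(1.0 / delta_c)) - 1
    ladder = delta_c * np.arange(1, m + 1)
    # flip (cos -> CDF) and interpolate cos at the CDF ladder; the CDF is
    # non-decreasing so np.interp is well defined (flat spans map to the left edge)
    cos_at = np.interp(ladder, cdf, cos_grid)
    return InverseCdfTable(grid=ladder, cos_theta=cos_at, delta_c=delta_c, label=label)


def sample_cos_theta(table: InverseCdfTable, uniforms) -> np.ndarray:
    """Map uniform variates in ``[0, 1)`` through the inverse-CDF table."""
    u = np.asarray(uniforms, dtype=float)
    if np.any(u < 0.0) or np.any(u >= 1.0):
        raise ValueError("uniform variates must lie in [0, 1)")
    out = np.interp(u, table.grid, table.cos_theta)
    return np.clip(out, -1.0, 1.0)


def save_params(params, path) -> None:
    """Write SPF parameters as flat key-value text."""
    if isinstance(params, SthgParams):
        lines = [f"g = {params.g!r}"]
    elif isinstance(params, TtHGParams):
        lines = [f"alpha = {params.alpha!r}", f"gf = {params.gf!r}",
                 f"gb = {params.gb!r}"]
    else:
        raise TypeError(f"unsupported parameters: {params!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_params(path):
    """Read SPF parameters written by :func:`save_params`."""
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                key, _, val = line.partition("=")
                kv[key.strip()] = float(val)
    if set(kv) == {"g"}:
        return SthgParams(**kv)
    if set(kv) == {"alpha", "gf", "gb"}:
        return TtHGParams(**kv)
    raise ValueError(f"unrecognized SPF parameter file with keys {sorted(kv)}")


def sthg_inverse_cdf(g: float, c) -> np.ndarray:
    """Closed-form stHG quantile: deflection cosine at CDF value ``c``.

    For ``g != 0``:  ``cos t = (1 + g^2 - ((1-g^2)/(1-g+2gc))^2) / (2g)``.
    """
    c = np.asarray(c, dtype=float)
    if g == 0.0:
        return 2.0 * c - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * c)
    return (1.0 + g * g - s * s) / (2.0 * g)
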