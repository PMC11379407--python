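"""Shared test utilities: direct-SFDI simulation wrapper and SE estimates."""

from __future__ import annotations

import numpy as np

from sfdimc.transport import (
    TransportConfig,
    demod_three_phase,
    simulate_sfdi_pattern,
)

PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


def direct_sfdi(
    spf,
    g1: float,
    fx: float,
    mua: float,
    mus_prime: float = 5.0,
    n_photons: int = 20_000,
    seed: int = 0,
    depth_factor: float = 8.0,
    bins_per_period: int = 25,
):
    """Three-phase direct simulation of patterned illumination at one ``fx``.

    Returns ``(pair, se_dc, se_ac)`` where the standard errors follow from
    the per-run weight tallies (variance of the spatial-mean profile; the
    three-phase AC combination carries ~sqrt(3) of that).
    """
    profs = []
    for k, phase in enumerate(PHASES):
        cfg = TransportConfig.from_reduced(
            mua=mua,
            mus_prime=mus_prime,
            g1=g1,
            spf=spf,
            n_medium=1.56,
            t_max=50.0,
            n_photons=n_photons,
            seed=seed + k,
        )
        profs.append(
            simulate_sfdi_pattern(
                cfg, fx, phase, depth_factor=depth_factor,
                bins_per_period=bins_per_period,
            )
        )
    pair = demod_three_phase(
        profs[0].profile, profs[1].profile, profs[2].profile, fx
    )
    var_mean = [
        (p.sum_w2 / p.n_photons - (p.sum_w / p.n_photons) ** 2) / p.n_photons
        for p in profs
    ]
    se_dc = float(np.sqrt(sum(var_mean)) / 3.0)
    se_ac = float(np.sqrt(sum(var_mean)))
    return pair, se_dc, se_ac


def bin_average_factor(bins_per_period: int) -> float:
    """Attenuation of a cosine averaged over one profile bin, sinc(pi/B)."""
    return float(np.sinc(1.0 / bins_per_period))


def isotropic_halfspace_reflectance_oracle(
    mua: float, mus: float, n_medium: float, n_photons: int, seed: int
):
    """Analog (unweighted) isotropic-scattering reference Monte Carlo.

    Deliberately a different code path from the transport kernel: vectorized
    numpy, analog survival sampling at each interaction, z-coordinate only.
    Returns (diffuse reflectance per launched photon, standard error).
    """
    rng = np.random.default_rng(seed)
    mut = mua + mus
    albedo = mus / mut
    spec = ((n_medium - 1.0) / (n_medium + 1.0)) ** 2

    n_enter = rng.random(n_photons) >= spec
    n_active = int(n_enter.sum())
    z = np.zeros(n_active)
    uz = np.ones(n_active)
    escaped = 0
    while z.size:
        step = -np.log(rng.random(z.size)) / mut
        z_new = z + uz * step
        crossing = z_new < 0.0
        # Fresnel decision at the surface for crossing photons
        cos_i = -uz[crossing]
        sin_t2 = (n_medium**2) * (1.0 - cos_i**2)
        refl = np.ones(cos_i.size)
        open_ch = sin_t2 < 1.0
        if np.any(open_ch):
            ci = cos_i[open_ch]
            ct = np.sqrt(1.0 - sin_t2[open_ch])
            rs = (n_medium * ci - ct) / (n_medium * ci + ct)
            rp = (n_medium * ct - ci) / (n_medium * ct + ci)
            refl[open_ch] = 0.5 * (rs**2 + rp**2)
        leaves = rng.random(cos_i.size) < (1.0 - refl)
        escaped += int(leaves.sum())
        # reflected photons bounce at z=0 and continue the remaining step
        idx = np.where(crossing)[0][~leaves]
        z_new[idx] = -z_new[idx]
        uz_new = uz.copy()
        uz_new[idx] = -uz_new[idx]
        keep = np.ones(z.size, dtype=bool)
        keep[np.where(crossing)[0][leaves]] = False
        z, uz = z_new[keep], uz_new[keep]
        # analog absorption at the interaction site, isotropic redirection
        survive = rng.random(z.size) < albedo
        z, uz = z[survive], uz[survive]
        uz = 2.0 * rng.random(z.size) - 1.0
    r = escaped / n_photons
    return r, np.sqrt(r * (1.0 - r) / n_photons)
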