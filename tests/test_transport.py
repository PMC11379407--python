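"""Monte Carlo photon transport: conservation, boundaries, demodulation."""

import numpy as np
import pytest

from sfdimc.transport import (
    SIDE_TOP,
    ReflectancePair,
    TransportConfig,
    demod_three_phase,
    propagate_pencil,
    simulate_sfdi_pattern,
    simulate_slab,
)

from tests.helpers import isotropic_halfspace_reflectance_oracle


class TestPencilHalfSpace:
    def test_index_matched_conservation(self, icdf_iso):
        # non-absorbing, index-matched: essentially everything escapes
        cfg = TransportConfig.from_reduced(
            mua=0.0, mus_prime=10.0, g1=0.0, spf=icdf_iso,
            n_medium=1.0, n_outside=1.0, t_max=300.0, n_photons=20_000, seed=5,
        )
        led = propagate_pencil(cfg).ledger()
        assert led["top"] >= 0.99
        assert led["top"] + led["time_cap"] == pytest.approx(1.0, abs=1e-12)

    def test_exit_contract(self, icdf_iso):
        cfg = TransportConfig.from_reduced(
            mua=0.05, mus_prime=5.0, g1=0.0, spf=icdf_iso,
            n_medium=1.56, t_max=10.0, n_photons=5_000, seed=6,
        )
        rec = propagate_pencil(cfg)
        assert np.all(rec.radius >= 0.0)
        assert np.all(rec.time_of_flight <= cfg.t_max + 1e-12)
        top = rec.escaped_top()
        assert np.all((top.weight > 0.0) & (top.weight <= 1.0))

    def test_seed_determinism(self, icdf_tthg):
        from tests.conftest import ZNO_TTHG

        def run():
            cfg = TransportConfig.from_reduced(
                mua=0.1, mus_prime=5.0, g1=ZNO_TTHG.g1, spf=icdf_tthg,
                n_medium=1.56, t_max=10.0, n_photons=2_000, seed=42,
            )
            return propagate_pencil(cfg)

        a, b = run(), run()
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.time_of_flight, b.time_of_flight)
        assert np.array_equal(a.side, b.side)

    def test_against_independent_isotropic_oracle(self, icdf_iso):
        """Total diffuse reflectance vs an analog, vectorized reference MC."""
        mua, musp, n = 0.1, 10.0, 40_000
        cfg = TransportConfig.from_reduced(
            mua=mua, mus_prime=musp, g1=0.0, spf=icdf_iso,
            n_medium=1.56, t_max=300.0, n_photons=n, seed=7,
            weight_cutoff=1e-7,
        )
        rec = propagate_pencil(cfg)
        led = rec.ledger()
        r_ours = led["top"]
        w_top = rec.weight[rec.side == SIDE_TOP]
        se_ours = np.sqrt(
            max(float((w_top**2).sum()) / n - r_ours**2, 0.0) / n
        )
        r_ref, se_ref = isotropic_halfspace_reflectance_oracle(
            mua, musp, 1.56, n_photons=60_000, seed=8
        )
        assert abs(r_ours - r_ref) < 3.0 * np.hypot(se_ours, se_ref)

    def test_anisotropy_neutrality_of_total_reflectance(
        self, icdf_sthg_low, icdf_sthg_high
    ):
        """Equal mus' gives near-identical total reflectance for g=0.84 vs 0.983."""
        rs = []
        ses = []
        for spf, g1, n in ((icdf_sthg_low, 0.84, 20_000), (icdf_sthg_high, 0.983, 8_000)):
            cfg = TransportConfig.from_reduced(
                mua=0.01, mus_prime=5.0, g1=g1, spf=spf,
                n_medium=1.56, t_max=50.0, n_photons=n, seed=9,
                weight_cutoff=1e-6,
            )
            led = propagate_pencil(cfg).ledger()
            rs.append(led["top"])
            ses.append(np.sqrt(led["top"] * (1 - led["top"]) / n))
        assert abs(rs[0] - rs[1]) < 3.0 * np.hypot(*ses)


class TestSlab:
    def test_clear_slab_full_transmission(self, icdf_iso):
        cfg = TransportConfig(
            mua=0.0, mus=0.0, spf=icdf_iso, n_medium=1.0, n_outside=1.0,
            n_photons=1_000, seed=1,
        )
        res = simulate_slab(cfg, thickness=1.0)
        assert res.transmittance == 1.0

    def test_ballistic_beer_lambert(self, icdf_iso):
        # mus=0, mua*L=1: weighted absorption makes T = exp(-1) exactly
        cfg = TransportConfig(
            mua=1.0, mus=0.0, spf=icdf_iso, n_medium=1.0, n_outside=1.0,
            n_photons=2_000, seed=2,
        )
        res = simulate_slab(cfg, thickness=1.0)
        assert res.transmittance == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_energy_ledger_closes(self, icdf_tthg):
        from tests.conftest import ZNO_TTHG

        cfg = TransportConfig.from_reduced(
            mua=0.3, mus_prime=1.6, g1=ZNO_TTHG.g1, spf=icdf_tthg,
            n_medium=1.56, t_max=50.0, n_photons=20_000, seed=3,
        )
        res = simulate_slab(cfg, thickness=1.0)
        total = res.reflectance + res.transmittance + res.absorbed + res.dropped
        assert total == pytest.approx(1.0, abs=1e-9)
        assert res.transflectance == pytest.approx(1.0 - res.absorbed)


class TestPattern:
    def test_dc_limit_profile_tracks_illumination(self, icdf_iso):
        """As fx -> 0 the exit profile approaches the illumination pattern
        itself (the AC reflectance approaches the DC value), so the profile
        divided by the pattern is flat within counting noise."""
        cfg = TransportConfig.from_reduced(
            mua=0.1, mus_prime=2.0, g1=0.0, spf=icdf_iso,
            n_medium=1.56, t_max=50.0, n_photons=30_000, seed=4,
        )
        fx = 0.05
        prof = simulate_sfdi_pattern(cfg, fx=fx, phase=0.0)
        pattern = 1.0 + np.cos(2.0 * np.pi * fx * prof.x)
        keep = pattern > 0.5  # skip near-dark bins where noise blows up
        ratio = prof.profile[keep] / pattern[keep]
        assert np.max(np.abs(ratio / ratio.mean() - 1.0)) < 0.35

    def test_phase_shift_translates_profile(self, icdf_iso):
        """Profiles at shifted phases agree after cyclic translation (in
        expectation); checked loosely on the spatial mean and the location
        of the maximum of a smoothed profile."""
        cfg = dict(mua=0.5, mus_prime=2.0, g1=0.0, n_medium=1.56,
                   t_max=50.0, n_photons=30_000)
        fx = 0.5
        p0 = simulate_sfdi_pattern(
            TransportConfig.from_reduced(spf=icdf_iso, seed=21, **cfg),
            fx, 0.0, bins_per_period=24,
        )
        p1 = simulate_sfdi_pattern(
            TransportConfig.from_reduced(spf=icdf_iso, seed=22, **cfg),
            fx, np.pi, bins_per_period=24,
        )
        assert p0.profile.mean() == pytest.approx(p1.profile.mean(), rel=0.05)
        # a pi phase shift is exactly half a period = 12 bins
        c = np.corrcoef(p0.profile, np.roll(p1.profile, 12))[0, 1]
        assert c > 0.9

    def test_degenerate_domain_rejected(self, icdf_iso):
        cfg = TransportConfig.from_reduced(
            mua=0.1, mus_prime=2.0, g1=0.0, spf=icdf_iso, n_photons=10, seed=0
        )
        with pytest.raises(ValueError):
            simulate_sfdi_pattern(cfg, fx=0.0, phase=0.0)


class TestDemodThreePhase:
    def test_constant_field(self):
        c = np.full(50, 0.37)
        pair = demod_three_phase(c, c, c)
        assert pair.dc == pytest.approx(0.37)
        assert pair.ac == pytest.approx(0.0, abs=1e-12)

    def test_analytic_sinusoids_recovered_exactly(self):
        x = np.linspace(0.0, 2.0, 100, endpoint=False)
        r0, r1, fx, phi = 0.6, 0.22, 1.5, 0.3
        fields = [
            r0 + r1 * np.cos(2 * np.pi * fx * x + phi + k)
            for k in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
        ]
        pair = demod_three_phase(*fields, fx=fx)
        assert pair.dc == pytest.approx(r0, abs=1e-12)
        assert pair.ac == pytest.approx(r1, abs=1e-12)

    def test_noisy_recovery_within_error(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0.0, 2.0, 200, endpoint=False)
        r0, r1, sigma = 0.5, 0.2, 0.01
        fields = [
            r0 + r1 * np.cos(2 * np.pi * x + k) + sigma * rng.standard_normal(x.size)
            for k in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
        ]
        pair = demod_three_phase(*fields)
        se = sigma / np.sqrt(x.size)
        assert abs(pair.dc - r0) < 3 * se
        assert abs(pair.ac - r1) < 3 * np.sqrt(3.0) * se

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            demod_three_phase(np.zeros(5), np.zeros(5), np.zeros(4))
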