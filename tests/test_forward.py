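"""White-MC record construction, property scaling, Hankel transform, LUTs."""

import numpy as np
import pytest
from scipy.special import j0

from sfdimc.forward import (
    BinSpec,
    RadialReflectance,
    WhiteMCRecord,
    apply_props,
    bin_records,
    build_lut,
    hankel_rd,
    predict_pair,
    predict_pair_with_se,
)
from sfdimc.forward import _edges_from_centers
from sfdimc.transport import ExitRecords, TransportConfig, propagate_pencil

from tests.conftest import ZNO_TTHG
from tests.helpers import bin_average_factor, direct_sfdi


def _records_from_arrays(radius, time, weight, config, n_launched):
    r = np.asarray(radius, dtype=float)
    return ExitRecords(
        x=r,
        y=np.zeros_like(r),
        time_of_flight=np.asarray(time, dtype=float),
        weight=np.asarray(weight, dtype=float),
        side=np.zeros(r.size, dtype=np.int8),
        absorbed=0.0,
        n_launched=n_launched,
        config=config,
    )


@pytest.fixture()
def dummy_config(icdf_iso):
    return TransportConfig.from_reduced(
        mua=1e-8, mus_prime=10.0, g1=0.0, spf=icdf_iso, n_photons=10, seed=0
    )


class TestBinRecords:
    def test_single_record_single_cell(self, dummy_config):
        rec = _records_from_arrays([1.0], [1.0], [1.0], dummy_config, 1)
        wmc = bin_records(rec)
        assert wmc.counts.sum() == 1.0
        assert np.count_nonzero(wmc.counts) == 1
        i, k = np.nonzero(wmc.counts)
        assert wmc.r_centers[i[0]] == pytest.approx(1.0, rel=0.01)
        assert wmc.t_centers[k[0]] == pytest.approx(1.0, rel=0.01)

    def test_weight_conservation_with_guard(self, dummy_config):
        # one photon inside the binned domain, one far outside
        rec = _records_from_arrays(
            [1.0, 500.0], [1.0, 1.0], [1.0, 1.0], dummy_config, 2
        )
        wmc = bin_records(rec)
        assert wmc.counts.sum() + wmc.out_of_range == pytest.approx(2.0)
        assert wmc.out_of_range == pytest.approx(1.0)

    def test_histogram_sums_to_detected_photons(self, wmc_tthg):
        # near-lossless base run with unit weights: binned + guard = escapes
        assert wmc_tthg.counts.sum() + wmc_tthg.out_of_range <= wmc_tthg.n_launched
        assert wmc_tthg.counts.sum() > 0.9 * wmc_tthg.n_launched

    def test_non_log_spaced_bins_rejected(self):
        lin = np.linspace(0.1, 10.0, 50)
        with pytest.raises(ValueError):
            WhiteMCRecord(
                counts=np.zeros((50, 50)), r_centers=lin, t_centers=lin,
                n_launched=1,
            )


class TestApplyProps:
    def test_identity_at_base_properties(self, wmc_tthg):
        prof = apply_props(wmc_tthg, 0.0, wmc_tthg.base_mus_prime)
        expected = wmc_tthg.counts.sum(axis=1) / wmc_tthg.n_launched
        assert np.allclose(prof.weight_fraction, expected)
        assert np.allclose(prof.rho, wmc_tthg.r_centers)

    @pytest.mark.parametrize("beta", [0.25, 1.0, 4.0])
    def test_plane_integral_invariant_without_absorption(self, wmc_tthg, beta):
        prof = apply_props(wmc_tthg, 0.0, beta * wmc_tthg.base_mus_prime)
        base = apply_props(wmc_tthg, 0.0, wmc_tthg.base_mus_prime)
        assert prof.total == pytest.approx(base.total, rel=1e-12)

    def test_beer_lambert_cell_factors(self, dummy_config):
        """Doubling mua squares every cell's absorption factor (single-cell
        record makes the factor directly observable)."""
        rec = _records_from_arrays([1.0], [1.0], [1.0], dummy_config, 1)
        wmc = bin_records(rec)
        k = np.nonzero(wmc.counts)[1][0]
        t_cell = wmc.t_centers[k]
        f1 = apply_props(wmc, 0.1, 10.0).total
        f2 = apply_props(wmc, 0.2, 10.0).total
        assert f2 == pytest.approx(f1 * np.exp(-0.1 * wmc.speed * t_cell), rel=1e-9)
        assert f2 == pytest.approx(f1**2, rel=1e-9)  # since launch weight is 1


class TestHankel:
    def test_fx_zero_is_plane_integral(self, wmc_tthg):
        prof = apply_props(wmc_tthg, 0.05, 2.0)
        assert hankel_rd(prof, 0.0) == prof.total

    def test_point_source_flat_spectrum(self):
        rho = np.geomspace(1e-5, 150.0, 750)
        frac = np.zeros(750)
        frac[0] = 0.42  # all weight at essentially zero radius
        edges = _edges_from_centers(rho)
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        prof = RadialReflectance(
            rho=rho, rd_per_area=frac / areas, weight_fraction=frac,
            annulus_area=areas,
        )
        vals = [hankel_rd(prof, fx) for fx in (0.0, 0.4, 1.0, 2.0)]
        assert np.allclose(vals, 0.42, rtol=1e-6)

    def test_exponential_profile_closed_form(self):
        # R(rho) = exp(-s rho) has Hankel transform 2 pi s/(s^2+k^2)^(3/2)
        s = 2.0
        rho = np.geomspace(1e-5, 150.0, 750)
        edges = _edges_from_centers(rho)
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        rd = np.exp(-s * rho)
        prof = RadialReflectance(
            rho=rho, rd_per_area=rd, weight_fraction=rd * areas,
            annulus_area=areas,
        )
        for fx in (0.0, 0.3, 1.0):
            k = 2.0 * np.pi * fx
            exact = 2.0 * np.pi * s / (s**2 + k**2) ** 1.5
            assert hankel_rd(prof, fx) == pytest.approx(exact, rel=5e-3)


class TestPredictPair:
    def test_dc_bounds_ac_on_property_grid(self, wmc_tthg):
        for mua in np.geomspace(0.01, 2.0, 6):
            for musp in np.geomspace(0.5, 8.0, 6):
                pair = predict_pair(wmc_tthg, mua, musp, 0.5)
                assert pair.dc >= pair.ac

    def test_rd_monotone_nonincreasing_in_fx(self, wmc_tthg):
        prof = apply_props(wmc_tthg, 0.05, 2.0)
        fxs = np.linspace(0.0, 1.0, 11)
        vals = [hankel_rd(prof, fx) for fx in fxs]
        assert np.all(np.diff(vals) <= 1e-12)

    @pytest.mark.parametrize("mua,label", [(0.01, "diffuse"), (1.0, "sub-diffuse")])
    def test_agrees_with_direct_simulation(self, wmc_tthg, icdf_tthg, mua, label):
        """wMC prediction vs three-phase demodulated direct simulation."""
        for i, fx in enumerate((0.3, 1.0)):
            pair, se = predict_pair_with_se(wmc_tthg, mua, 5.0, fx)
            direct, se_dc, se_ac = direct_sfdi(
                icdf_tthg, ZNO_TTHG.g1, fx, mua,
                n_photons=20_000, seed=500 + 10 * i + int(mua * 10),
            )
            assert abs(direct.dc - pair.dc) < 3.0 * np.hypot(se["dc"], se_dc)
            expected_ac = pair.ac * bin_average_factor(25)
            assert abs(direct.ac - expected_ac) < 3.0 * np.hypot(se["ac"], se_ac)


class TestScalingLaw:
    @pytest.mark.parametrize("beta,seed", [(0.5, 201), (2.0, 202)])
    def test_apply_props_equals_rescaled_transport(
        self, wmc_tthg, icdf_tthg, beta, seed
    ):
        musp = beta * wmc_tthg.base_mus_prime
        cfg = TransportConfig.from_reduced(
            mua=1e-8, mus_prime=musp, g1=ZNO_TTHG.g1, spf=icdf_tthg,
            n_medium=1.56, t_max=3.0 / beta, n_photons=100_000, seed=seed,
        )
        native = bin_records(propagate_pencil(cfg))
        for fx in (0.3, 1.0):
            pa, sa = predict_pair_with_se(wmc_tthg, 0.05, musp, fx)
            pb, sb = predict_pair_with_se(native, 0.05, musp, fx)
            assert abs(pa.dc - pb.dc) < 3.0 * np.hypot(sa["dc"], sb["dc"])
            assert abs(pa.ac - pb.ac) < 3.0 * np.hypot(sa["ac"], sb["ac"])


class TestInversionLut:
    def test_roundtrip_interior(self, wmc_tthg, lut_tthg):
        for mua, musp in ((0.05, 1.0), (0.1, 2.0), (0.5, 3.0), (1.0, 1.5)):
            pair = predict_pair(wmc_tthg, mua, musp, lut_tthg.fx)
            a, s, undet = lut_tthg.lookup(pair.dc, pair.ac)
            assert not undet
            assert float(a) == pytest.approx(mua, rel=0.02)
            assert float(s) == pytest.approx(musp, rel=0.02)

    def test_unphysical_nodes_flagged(self, lut_tthg):
        i = np.argmin(np.abs(lut_tthg.dc_grid - 0.01))
        k = np.argmin(np.abs(lut_tthg.ac_grid - 0.05))
        assert lut_tthg.ac_grid[k] > lut_tthg.dc_grid[i]
        assert lut_tthg.flagged[i, k]

    def test_spf_surfaces_differ_most_at_high_ac_dc(self, lut_tthg, lut_sthg_low):
        both = ~lut_tthg.flagged & ~lut_sthg_low.flagged
        dcg, acg = np.meshgrid(
            lut_tthg.dc_grid, lut_tthg.ac_grid, indexing="ij"
        )
        ratio = acg / dcg
        diff = np.abs(
            np.log(lut_tthg.mus_prime_surface / lut_sthg_low.mus_prime_surface)
        )
        top = both & (ratio > 0.6)
        bottom = both & (ratio < 0.1)
        assert top.sum() > 100 and bottom.sum() > 100
        assert np.nanmedian(diff[top]) > np.nanmedian(diff[bottom])

    def test_hdf5_roundtrip(self, lut_tthg, tmp_path):
        path = tmp_path / "lut.h5"
        lut_tthg.to_hdf5(path)
        from sfdimc.forward import InversionLUT

        back = InversionLUT.from_hdf5(path)
        assert np.allclose(back.dc_grid, lut_tthg.dc_grid)
        assert np.array_equal(
            np.isnan(back.mua_surface), np.isnan(lut_tthg.mua_surface)
        )
        assert back.fx == lut_tthg.fx


class TestRecordIo:
    def test_hdf5_roundtrip(self, wmc_tthg, tmp_path):
        path = tmp_path / "wmc.h5"
        wmc_tthg.to_hdf5(path)
        back = WhiteMCRecord.from_hdf5(path)
        assert np.array_equal(back.counts, wmc_tthg.counts)
        assert back.n_launched == wmc_tthg.n_launched
        assert back.spf_label == wmc_tthg.spf_label


class TestSubDiffuseStructure:
    def test_tthg_backscatter_raises_early_counts(self, wmc_tthg, wmc_sthg_low):
        """The ttHG record has more remitted weight at short radii and times
        than the equal-g1 stHG record, and less at the distribution peak."""
        r = wmc_tthg.r_centers
        early = (r >= 0.005) & (r <= 0.1)
        peak = (r >= 0.3) & (r <= 1.0)
        rm_t = wmc_tthg.counts.sum(axis=1)
        rm_l = wmc_sthg_low.counts.sum(axis=1)
        assert rm_t[early].sum() > 1.1 * rm_l[early].sum()
        assert rm_t[peak].sum() < rm_l[peak].sum()
        t = wmc_tthg.t_centers
        early_t = (t >= 1e-5) & (t <= 1e-3)
        tm_t = wmc_tthg.counts.sum(axis=0)
        tm_l = wmc_sthg_low.counts.sum(axis=0)
        assert tm_t[early_t].sum() > 1.1 * tm_l[early_t].sum()
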