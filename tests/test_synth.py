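"""Synthetic-field generator: planted structure, determinism, statistics."""
import numpy as np
import pytest
from scipy import ndimage

import ecoregions as er


def _connected(label_map, k):
    comp, n = ndimage.label(label_map == k, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return n == 1


class TestTruth:
    def test_deterministic(self):
        cfg = er.SynthConfig(seed=7, nlat=20, nlon=20, n_years=5)
        t1, t2 = er.generate_truth(cfg), er.generate_truth(cfg)
        assert np.array_equal(t1.label_map, t2.label_map)
        assert t1.jets == t2.jets
        assert t1.couplings == t2.couplings
        s1 = er.generate_sst(t1, cfg)
        s2 = er.generate_sst(t2, cfg)
        assert np.array_equal(s1.values, s2.values, equal_nan=True)
        u1, v1 = er.generate_velocity(t1, cfg)
        u2, v2 = er.generate_velocity(t2, cfg)
        assert np.array_equal(u1.values, u2.values, equal_nan=True)
        assert np.array_equal(v1.values, v2.values, equal_nan=True)

    def test_single_region_has_no_jets(self):
        cfg = er.SynthConfig(n_regions=1, land_fraction=0.0, nlat=12, nlon=12,
                             n_years=3, seed=1)
        truth = er.generate_truth(cfg)
        assert set(np.unique(truth.label_map)) <= {0, 1}
        assert 1 in truth.label_map
        assert truth.jets == ()

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_regions_disjoint_connected_covering(self, seed):
        cfg = er.SynthConfig(seed=seed)
        truth = er.generate_truth(cfg)
        n_ocean = truth.mask.sum()
        covered = (truth.label_map > 0).sum()
        assert covered >= 0.5 * n_ocean
        for k in range(1, cfg.n_regions + 1):
            assert (truth.label_map == k).any()
            assert _connected(truth.label_map, k)

    def test_every_adjacent_pair_has_a_jet(self):
        cfg = er.SynthConfig(seed=5, n_regions=4, nlat=40, nlon=40)
        truth = er.generate_truth(cfg)
        lm = truth.label_map
        adjacent = set()
        for i in range(40):
            for j in range(40):
                a = lm[i, j]
                if a <= 0:
                    continue
                for ni, nj in ((i + 1, j), (i, j + 1)):
                    if ni < 40 and nj < 40:
                        b = lm[ni, nj]
                        if b > 0 and b != a:
                            adjacent.add((min(a, b), max(a, b)))
        jet_pairs = {j.regions for j in truth.jets}
        assert adjacent and adjacent == jet_pairs

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            er.generate_truth(er.SynthConfig(nlat=4, nlon=4, n_regions=10, n_years=2))

    def test_roundtrip(self, tmp_path, small_world):
        truth, _ = small_world
        er.save_truth(truth, tmp_path / "t.json", tmp_path / "t.nc")
        back = er.load_truth(tmp_path / "t.json")
        assert np.array_equal(back.label_map, truth.label_map)
        assert back.jets == truth.jets
        assert back.couplings == truth.couplings


class TestSST:
    def test_noiseless_cells_perfectly_correlated(self):
        cfg = er.SynthConfig(nlat=12, nlon=12, n_years=3, n_regions=1,
                             snr=1e9, seasonal_amp=0.0, trend=0.0, seed=2)
        truth = er.generate_truth(cfg)
        sst = er.generate_sst(truth, cfg)
        cells = truth.region_cells(1)[:6]
        series = np.array([sst.values[:, i, j] for i, j in cells])
        corr = np.corrcoef(series)
        assert np.allclose(corr, 1.0, atol=1e-6)

    def test_trend_slope_recovered(self):
        # the latent signal adds slope noise with a known standard error
        cfg = er.SynthConfig(nlat=8, nlon=8, n_years=30, n_regions=1, snr=1e9,
                             seasonal_amp=0.0, trend=0.5, ar1_coef=1e-9, seed=3)
        truth = er.generate_truth(cfg)
        sst = er.generate_sst(truth, cfg)
        T = sst.n_time
        t = np.arange(T)
        i, j = truth.region_cells(1)[0]
        slope = np.polyfit(t, sst.values[:, i, j], 1)[0]
        se = 1.0 / np.sqrt((T**3 - T) / 12)
        assert slope == pytest.approx(0.5 / 12, abs=3 * se)

    def test_coupling_lag_peak(self):
        cfg = er.SynthConfig(seed=4, n_years=30,
                             couplings=((1, 2, 3, 0.8),))
        truth = er.generate_truth(cfg)
        lat = er.generate_latents(truth, cfg)
        r = er.lagged_correlation(lat[0], lat[1], 12)
        lags = np.arange(-12, 13)
        assert lags[np.argmax(r)] == 3
        assert r[3 + 12] > 0.7

    @pytest.mark.parametrize("pair", [(0.5, 2.0), (2.0, 10.0)])
    def test_within_region_correlation_increases_with_snr(self, pair):
        means = []
        for snr in pair:
            cfg = er.SynthConfig(nlat=16, nlon=16, n_years=10, n_regions=1,
                                 snr=snr, seed=6)
            truth = er.generate_truth(cfg)
            anoms = er.anomalies(er.generate_sst(truth, cfg))
            cells = truth.region_cells(1)[:20]
            means.append(er.average_pairwise_correlation(anoms, cells))
        assert means[1] > means[0]

    def test_land_cells_carry_no_signal(self):
        cfg = er.SynthConfig(nlat=16, nlon=16, n_years=3, n_regions=2,
                             land_fraction=0.2, seed=8)
        truth = er.generate_truth(cfg)
        sst = er.generate_sst(truth, cfg)
        assert (~truth.mask).sum() == round(0.2 * 16 * 16)
        assert np.isnan(sst.values[:, ~truth.mask]).all()
        assert (truth.label_map[~truth.mask] == 0).all()


class TestVelocity:
    def test_no_jets_background_only(self):
        cfg = er.SynthConfig(n_regions=1, nlat=12, nlon=12, n_years=3, seed=9)
        truth = er.generate_truth(cfg)
        u, v = er.generate_velocity(truth, cfg)
        speed = np.sqrt(np.nanmean(u.values**2 + v.values**2, axis=0))
        bg_max = cfg.jet_speed * cfg.background_speed_fraction * 1.5
        assert np.nanmax(speed) < bg_max * 1.1

    def test_jet_ke_closed_form(self, small_cfg, small_world):
        truth, _ = small_world
        u, v = er.generate_velocity(truth, small_cfg)
        ke = er.kinetic_energy(u, v)
        jm = truth.jet_mask(small_cfg.jet_halfwidth)
        assert jm.any()
        jet_ke = np.nanmean(ke.values[:, jm])
        assert jet_ke == pytest.approx(small_cfg.jet_speed**2 / 2, rel=0.05)
        # jets at least 5x faster than background
        bg = truth.mask & ~jm
        assert jet_ke > 25 * np.nanmean(ke.values[:, bg])

    def test_front_mask_contains_jets(self, small_cfg, small_world):
        truth, _ = small_world
        u, v = er.generate_velocity(truth, small_cfg)
        ke = er.kinetic_energy(u, v)
        fm = er.front_mask(ke, er.ke_threshold(ke, 50), 50)
        jm = truth.jet_mask(small_cfg.jet_halfwidth)
        assert (fm.values & jm).sum() >= 0.95 * jm.sum()

    def test_zero_on_land(self):
        cfg = er.SynthConfig(nlat=16, nlon=16, n_years=3, n_regions=2,
                             land_fraction=0.2, seed=8)
        truth = er.generate_truth(cfg)
        u, v = er.generate_velocity(truth, cfg)
        assert np.isnan(u.values[:, ~truth.mask]).all()
        assert np.isnan(v.values[:, ~truth.mask]).all()
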