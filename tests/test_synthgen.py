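"""Generator invariants: determinism, seasonality, memory structure, masks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluxmem.synthgen import (
    BANDS,
    ConfigurationError,
    GeneratorConfig,
    SiteRecord,
    apply_observation_model,
    generate_dataset,
    generate_sites,
    memory_half_life,
    potential_radiation,
    simulate_climate,
    simulate_nee,
    simulate_vegetation,
    write_dataset,
)


def noiseless(**kw) -> GeneratorConfig:
    return GeneratorConfig(
        noise_tair=0, noise_rg=0, noise_vpd=0, noise_precip_sigma=0,
        noise_greenness=0, noise_reflectance=0, noise_tir=0, noise_nee=0,
        **kw,
    )


def make_site(latitude=45.0, pft="deciduous", disturbance_year=None) -> SiteRecord:
    return SiteRecord(
        site_id="SYN0000", latitude=latitude, pft=pft,
        climate_class="temperate", age_1982=50.0,
        disturbance_year=disturbance_year,
        window_start=(2000, 1), window_end=(2009, 12),
    )


class TestSites:
    def test_empty_request_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_sites(GeneratorConfig(n_sites=0))

    def test_short_period_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(period=(2000, 2003)).validate()

    def test_seeded_determinism(self):
        a = generate_sites(GeneratorConfig(n_sites=12, master_seed=5))
        b = generate_sites(GeneratorConfig(n_sites=12, master_seed=5))
        assert a == b

    def test_adding_sites_preserves_existing(self):
        a = generate_sites(GeneratorConfig(n_sites=10, master_seed=5))
        b = generate_sites(GeneratorConfig(n_sites=20, master_seed=5))
        assert a == b[:10]

    def test_disturbance_count_within_binomial_band(self):
        sites = generate_sites(
            GeneratorConfig(n_sites=200, disturbance_prob=0.25, master_seed=1)
        )
        k = sum(s.disturbance_year is not None for s in sites)
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.25)
        assert lo <= k <= hi

    def test_windows_inside_period(self):
        for s in generate_sites(GeneratorConfig(n_sites=30, master_seed=2)):
            assert 1982 <= s.window_start[0] <= s.window_end[0] <= 2015
            span = s.window_end[0] - s.window_start[0] + 1
            assert 3 <= span <= 12


class TestClimate:
    def test_hemisphere_phase_offset(self):
        cfg = noiseless()
        north = simulate_climate(make_site(latitude=45.0), cfg)
        south = simulate_climate(make_site(latitude=-45.0), cfg)
        m_n = north.groupby("month")["tair"].mean().idxmax()
        m_s = south.groupby("month")["tair"].mean().idxmax()
        assert (m_n - m_s) % 12 == 6

    def test_hemisphere_amplitude_unchanged(self):
        cfg = noiseless()
        north = simulate_climate(make_site(latitude=45.0), cfg)
        south = simulate_climate(make_site(latitude=-45.0), cfg)
        for v in ("tair", "rg"):
            assert np.isclose(north[v].max() - north[v].min(),
                              south[v].max() - south[v].min())

    def test_noise_free_series_periodic(self):
        clim = simulate_climate(make_site(), noiseless())
        for v in ("tair", "precip", "rg", "vpd", "rpot"):
            x = clim[v].to_numpy()
            assert np.allclose(x[12:], x[:-12])

    def test_rpot_amplitude_grows_with_latitude(self):
        months = np.arange(1, 13)
        eq = potential_radiation(0.0, months)
        mid = potential_radiation(45.0, months)
        assert eq.max() - eq.min() < mid.max() - mid.min()

    def test_vpd_monotone_in_temperature(self):
        clim = simulate_climate(make_site(), noiseless())
        order = np.argsort(clim["tair"].to_numpy())
        assert np.all(np.diff(clim["vpd"].to_numpy()[order]) >= 0)

    def test_precip_nonnegative(self):
        clim = simulate_climate(make_site(), GeneratorConfig())
        assert (clim["precip"] >= 0).all()


class TestVegetation:
    def test_noise_free_greenness_periodic(self):
        g, _ = simulate_vegetation(make_site(), simulate_climate(make_site(), noiseless()), noiseless())
        assert np.allclose(g[12:], g[:-12])

    def test_pft_amplitude_ordering(self):
        cfg = noiseless()
        amps = {}
        for pft in ("deciduous", "mixed", "evergreen"):
            site = make_site(pft=pft)
            g, _ = simulate_vegetation(site, simulate_climate(site, cfg), cfg)
            amps[pft] = g.max() - g.min()
        assert amps["deciduous"] > amps["mixed"] > amps["evergreen"]

    def test_exponential_recovery_fraction(self):
        cfg = noiseless(recovery_tau=24.0, disturbance_drop=0.5)
        site = make_site(disturbance_year=2003)
        clim = simulate_climate(site, cfg)
        g_dist, _ = simulate_vegetation(site, clim, cfg)
        g_ref, _ = simulate_vegetation(make_site(), clim, cfg)
        t0 = np.flatnonzero(g_ref - g_dist)[0]
        drop = g_ref[t0] - g_dist[t0]
        recovered = 1.0 - (g_ref[t0 + 24] - g_dist[t0 + 24]) / drop
        assert np.isclose(recovered, 1.0 - np.exp(-1.0), atol=1e-9)

    def test_nir_perfectly_tracks_greenness_without_noise(self):
        cfg = noiseless()
        site = make_site()
        g, bands = simulate_vegetation(site, simulate_climate(site, cfg), cfg)
        assert np.isclose(np.corrcoef(g, bands["nir"])[0, 1], 1.0)

    def test_reflectance_in_unit_interval(self):
        cfg = GeneratorConfig()
        site = make_site()
        _, bands = simulate_vegetation(site, simulate_climate(site, cfg), cfg)
        for b in BANDS[:-1]:
            assert bands[b].between(0, 1).all()


class TestNEE:
    def _const_climate(self, n=72, tair=15.0, rg=200.0, vpd=10.0):
        return pd.DataFrame(
            {"year": np.repeat(np.arange(2000, 2000 + n // 12), 12),
             "month": np.tile(np.arange(1, 13), n // 12),
             "tair": tair, "precip": 50.0, "rg": rg, "vpd": vpd, "rpot": 300.0}
        )

    def test_zero_light_use_means_noise_only(self):
        cfg = noiseless(gpp_light_use=0.0)
        clim = self._const_climate()
        nee = simulate_nee(make_site(), clim, np.full(len(clim), 0.5), cfg)
        assert np.allclose(nee["gpp"], 0.0)
        assert np.allclose(nee["nee"], 0.0)  # zero pool influx, zero noise

    def test_full_decay_full_gain_is_pure_lag(self):
        cfg = noiseless(pool_decay=1.0, pool_gain=1.0)
        site = make_site()
        clim = simulate_climate(site, cfg)
        g, _ = simulate_vegetation(site, clim, cfg)
        nee = simulate_nee(site, clim, g, cfg)
        gpp = nee["gpp"].to_numpy()
        pool = nee["pool"].to_numpy()
        assert np.allclose(pool[1:], gpp[:-1])

    def test_pool_reaches_geometric_series_limit(self):
        cfg = noiseless(pool_decay=0.2, pool_gain=1.0)
        clim = self._const_climate()
        g = np.full(len(clim), 0.5)
        nee = simulate_nee(make_site(), clim, g, cfg)
        gpp = nee["gpp"].to_numpy()
        assert np.allclose(gpp, gpp[0])
        assert np.isclose(nee["pool"].iloc[60], gpp[0] / 0.2, rtol=1e-6)

    def test_infinite_memory_pool_rejected_unless_requested(self):
        cfg = noiseless()
        cfg.pool_decay = 0.0
        clim = self._const_climate()
        with pytest.raises(ConfigurationError):
            simulate_nee(make_site(), clim, np.full(len(clim), 0.5), cfg)

    def test_memory_partial_correlation(self):
        """With lam<1 NEE retains dependence on last month's GPP beyond the
        current month's; with lam=1, gamma=0 that dependence vanishes."""

        def partial_corr(ds):
            rs = []
            for sid, tr in ds.truth.items():
                nee = ds.panels[sid]["nee"].to_numpy()
                ok = np.isfinite(nee[1:])
                g0, g1 = tr["gpp"].to_numpy()[1:][ok], tr["gpp"].to_numpy()[:-1][ok]
                y = nee[1:][ok]
                r_y = y - np.polyval(np.polyfit(g0, y, 1), g0)
                r_x = g1 - np.polyval(np.polyfit(g0, g1, 1), g0)
                rs.append(np.corrcoef(r_x, r_y)[0, 1])
            return np.mean(rs)

        base = dict(n_sites=5, period=(2000, 2011), master_seed=7, noise_nee=0.0)
        with_memory = generate_dataset(GeneratorConfig(**base))
        memoryless = generate_dataset(
            GeneratorConfig(**base, pool_decay=1.0, pool_gain=0.0)
        )
        assert partial_corr(with_memory) > 0.2
        assert abs(partial_corr(memoryless)) < 0.05

    def test_half_life_formula(self):
        assert np.isclose(memory_half_life(0.2), np.log(2) / -np.log(0.8))
        assert memory_half_life(1.0) == 0.0


class TestObservationModel:
    def test_no_gaps_no_missing(self):
        cfg = GeneratorConfig(gap_rate_reflectance=0.0, master_seed=3)
        site = make_site()
        site = SiteRecord(**{**site.__dict__, "window_start": (1982, 1), "window_end": (2015, 12)})
        panel = simulate_climate(site, cfg)
        g, bands = simulate_vegetation(site, panel, cfg)
        for b in BANDS:
            panel[b] = bands[b].to_numpy()
        panel["nee"] = simulate_nee(site, panel, g, cfg)["nee"].to_numpy()
        obs, _ = apply_observation_model(panel, site, cfg)
        assert not obs[list(BANDS) + ["nee"]].isna().any().any()

    def test_total_gap_rate_withholds_everything(self):
        cfg = GeneratorConfig(gap_rate_reflectance=1.0, master_seed=3)
        site = make_site()
        panel = simulate_climate(site, cfg)
        g, bands = simulate_vegetation(site, panel, cfg)
        for b in BANDS:
            panel[b] = bands[b].to_numpy()
        panel["nee"] = 0.0
        obs, truth = apply_observation_model(panel, site, cfg)
        for b in BANDS:
            assert obs[b].isna().all()
            assert truth[b].notna().all()

    def test_withheld_fraction_binomial(self):
        cfg = GeneratorConfig(
            n_sites=200, gap_rate_reflectance=0.3, tropical_gap_multiplier=1.0,
            master_seed=9,
        )
        ds = generate_dataset(cfg)
        n = sum(len(p) for p in ds.panels.values()) * len(BANDS)
        k = sum(p[list(BANDS)].isna().sum().sum() for p in ds.panels.values())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.3)
        assert lo <= k <= hi

    def test_nee_only_inside_window(self):
        ds = generate_dataset(GeneratorConfig(n_sites=5, master_seed=4))
        for s in ds.sites:
            p = ds.panels[s.site_id]
            ym = p["year"] * 12 + p["month"] - 1
            w0 = s.window_start[0] * 12 + s.window_start[1] - 1
            w1 = s.window_end[0] * 12 + s.window_end[1] - 1
            assert p.loc[(ym < w0) | (ym > w1), "nee"].isna().all()


class TestDataset:
    def test_panel_row_count(self):
        ds = generate_dataset(GeneratorConfig(n_sites=2, period=(1982, 2015), master_seed=0))
        for p in ds.panels.values():
            assert len(p) == 408
            ym = p["year"].to_numpy() * 12 + p["month"].to_numpy()
            assert np.all(np.diff(ym) == 1)  # no holes, no duplicates

    def test_serialized_outputs_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_sites=3, period=(2000, 2006), master_seed=13)
        ds1 = generate_dataset(cfg)
        ds2 = generate_dataset(cfg)
        write_dataset(ds1, tmp_path / "a")
        write_dataset(ds2, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_no_disturbance_no_greenness_breakpoint(self):
        """Changepoint scan on latent greenness: a split statistic over 12-month
        windows stays small without disturbances and fires with them."""

        def max_break(truth, panel):
            g = truth["greenness"].to_numpy()
            months = panel["month"].to_numpy()
            msc = np.array([g[months == m].mean() for m in range(1, 13)])
            a = g - msc[months - 1]  # deseasonalized
            return max(
                abs(a[t - 12 : t].mean() - a[t : t + 12].mean())
                for t in range(12, len(a) - 12)
            )

        sensitivity = 0.12  # greenness units; above AR-drift, below disturbance drops
        quiet = generate_dataset(
            GeneratorConfig(n_sites=6, period=(2000, 2011), disturbance_prob=0.0, master_seed=21)
        )
        assert all(
            max_break(quiet.truth[sid], quiet.panels[sid]) < sensitivity
            for sid in quiet.panels
        )
        shocked = generate_dataset(
            GeneratorConfig(n_sites=6, period=(2000, 2011), disturbance_prob=1.0,
                            disturbance_drop=0.7, master_seed=21)
        )
        assert any(
            max_break(shocked.truth[sid], shocked.panels[sid]) > sensitivity
            for sid in shocked.panels
        )
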