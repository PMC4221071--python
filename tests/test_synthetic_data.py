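"""The synthetic study system has the statistical structure the
analysis assumes: deterministic under a fixed seed, physically ordered,
and generated from recoverable closed forms."""

import numpy as np
import pytest

from whitebark import synthetic_data as synth
from whitebark.config import ScenarioSpec, SyntheticConfig
from whitebark.containers import CLIMATE_VARS


def _quiet_cfg(**kw) -> SyntheticConfig:
    """A climate config with all spatial/temporal noise switched off."""
    defaults = dict(
        grid_rows=16,
        grid_cols=16,
        years=(1950, 1959),
        temp_heterogeneity_c=0.0,
        winter_heterogeneity_multiplier=1.0,
        winter_lapse_factor=1.0,
        ppt_heterogeneity=0.0,
        dewpoint_depression_heterogeneity_c=0.0,
        interannual_temp_sd_c=0.0,
        interannual_ppt_cv=0.0,
        seed=3,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestTerrain:
    def test_values_span_configured_range(self):
        cfg = SyntheticConfig(grid_rows=24, grid_cols=24, elev_range_m=(500, 4200))
        dem = synth.make_terrain(cfg)
        assert dem.min() >= 500 and dem.max() <= 4200
        assert dem.min() == pytest.approx(500) and dem.max() == pytest.approx(4200)

    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticConfig(grid_rows=16, grid_cols=16, seed=11)
        assert np.array_equal(synth.make_terrain(cfg), synth.make_terrain(cfg))

    def test_single_bump_peaks_at_center(self):
        cfg = SyntheticConfig(grid_rows=21, grid_cols=21)
        dem = synth.make_terrain(cfg, bumps=[(8.0, 13.0, 1.0, 3.0)], plane_amplitude=0.0)
        assert np.unravel_index(np.argmax(dem), dem.shape) == (8, 13)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(grid_rows=4, grid_cols=4)


class TestClimate:
    def test_lapse_rate_forced_by_construction(self):
        """Two cells 1000 m apart differ by the lapse rate in every month
        (uniform-lapse, noise-free configuration)."""
        cfg = _quiet_cfg(lapse_rate_c_per_km=-6.5)
        dem = synth.make_terrain(cfg)
        cube = synth.make_climate(dem, cfg)
        flat_dem = dem.ravel()
        i, j = int(np.argmin(flat_dem)), int(np.argmax(flat_dem))
        delev_km = (flat_dem[j] - flat_dem[i]) / 1000.0
        tmean = cube.data["tmean"][0].reshape(12, -1)
        for m in range(12):
            assert tmean[m, j] - tmean[m, i] == pytest.approx(-6.5 * delev_km, abs=1e-9)

    def test_zero_interannual_noise_repeats_years(self):
        cfg = _quiet_cfg()
        cube = synth.make_climate(synth.make_terrain(cfg), cfg)
        for var in CLIMATE_VARS:
            assert np.allclose(cube.data[var], cube.data[var][0][None])

    def test_thirty_year_july_mean_matches_closed_form(self):
        """The 30-year July tmax normal equals the generator's seasonal
        closed form within 2 standard errors of the interannual noise."""
        cfg = _quiet_cfg(years=(1950, 1979), interannual_temp_sd_c=0.6, seed=5)
        dem = synth.make_terrain(cfg)
        cube = synth.make_climate(dem, cfg)
        normal = cube.data["tmax"][:, 6].mean(axis=0)
        expected = synth.seasonal_tmean(cfg, dem, 7) + cfg.diurnal_half_range_c
        se = 0.6 / np.sqrt(30)
        assert np.abs(normal - expected).max() < 2 * se + 1e-9

    def test_physical_ordering_everywhere(self, study):
        cube = study["climate"]
        assert np.all(cube.data["tmin"] <= cube.data["tmean"])
        assert np.all(cube.data["tmean"] <= cube.data["tmax"])
        assert np.all(cube.data["tdew"] <= cube.data["tmean"])
        assert np.all(cube.data["ppt"] >= 0)

    def test_empty_year_range_rejected(self):
        cfg = _quiet_cfg()
        with pytest.raises(ValueError):
            synth.make_climate(synth.make_terrain(cfg), cfg, years=(2000, 1999))


class TestSoil:
    def test_positive_and_thinning_with_elevation(self, study):
        awc, dem = study["awc"], study["dem"]
        assert awc.min() > 0
        bins = np.digitize(dem, np.quantile(dem, [0.25, 0.5, 0.75]))
        means = [awc[bins == b].mean() for b in range(4)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_reproducible(self, small_cfg, study):
        assert np.array_equal(study["awc"], synth.make_soil(study["dem"], small_cfg))


class TestVirtualSpecies:
    def test_probability_half_at_envelope_boundary(self, study):
        truth = study["truth"]
        # a point on the logistic boundary: solve beta0 + bt*zt + bp*zp = 0
        zt = -truth.beta0 / truth.beta_tmax7
        tmax7 = truth.tmax7_mean + zt * truth.tmax7_sd
        pack4 = np.expm1(truth.pack4_mean)  # z_p = 0
        assert truth.presence_probability(tmax7, pack4) == pytest.approx(0.5)

    def test_extreme_cold_limitation_restricts_to_coldest_cells(self, study):
        cfg = study["cfg"]
        strong = synth.VirtualSpeciesTruth(
            beta0=cfg.beta0,
            beta_tmax7=-300.0,
            beta_pack4=1e-6,
            tmax7_mean=study["truth"].tmax7_mean,
            tmax7_sd=study["truth"].tmax7_sd,
        )
        t = study["normals"]["tmax7"]
        p = strong.presence_probability(t, np.zeros_like(t))
        # in the hard-limit regime the envelope collapses to a step at its
        # boundary (the standardization mean): warm side empty, cold side full
        warm = t > strong.tmax7_mean + 0.2 * strong.tmax7_sd
        cold = t < strong.tmax7_mean - 0.2 * strong.tmax7_sd
        assert p[warm].max() < 1e-6
        assert p[cold].min() > 1 - 1e-6

    def test_empirical_presence_rate_matches_logistic(self, study):
        """Over 10,000 plots the presence count agrees with the generating
        logistic probabilities within a 99% binomial interval."""
        cfg, truth = study["cfg"], study["truth"]
        records = synth.sample_virtual_species(
            study["normals"], truth, study["dem"], study["geometry"],
            n_plots=10_000, seed=99, false_absence_fraction=0.0,
        )
        row, col = study["geometry"].xy_to_rowcol(
            records["x"].to_numpy(), records["y"].to_numpy()
        )
        p = truth.presence_probability(
            study["normals"]["tmax7"][row, col], study["normals"]["pack4"][row, col]
        )
        observed = records["present"].sum()
        sd = np.sqrt((p * (1 - p)).sum())
        assert abs(observed - p.sum()) < 2.576 * sd

    def test_too_few_plots_rejected(self, study):
        with pytest.raises(ValueError):
            synth.sample_virtual_species(
                study["normals"], study["truth"], study["dem"], study["geometry"],
                n_plots=19, seed=1,
            )

    def test_false_absence_injection_is_logged_and_collocated(self, study):
        records = study["records"]
        n_false = records.attrs["n_false_absences"]
        assert n_false > 0
        wlis = records[records["source"] == "WLIS"]
        assert len(wlis) == n_false
        assert (wlis["present"] == 1).all()


class TestGcmEnsemble:
    def test_zero_trend_zero_noise_repeats_climatology(self):
        cfg = _quiet_cfg(
            n_members=2,
            future_years=(1960, 1979),
            scenarios={"rcp45": ScenarioSpec(0.0, 0.0, 0.0, 0.0)},
        )
        dem = synth.make_terrain(cfg)
        base = synth.make_climate(dem, cfg)
        future = synth.make_gcm_ensemble(base, cfg, {"rcp45": cfg.scenarios["rcp45"]})
        member = future["rcp45"][0]
        clim = base.data["tmean"].mean(axis=0)
        assert np.allclose(member.data["tmean"], clim[None])

    def test_linear_trend_recovered_from_annual_means(self):
        """A noise-free 0.5 degC/decade member warms by exactly the trend."""
        cfg = _quiet_cfg(
            n_members=2,
            future_years=(1960, 2049),
            scenarios={"rcp85": ScenarioSpec(0.5, 0.0, 0.0, 0.0)},
        )
        dem = synth.make_terrain(cfg)
        base = synth.make_climate(dem, cfg)
        member = synth.make_gcm_ensemble(base, cfg, {"rcp85": cfg.scenarios["rcp85"]})[
            "rcp85"
        ][0]
        annual = member.data["tmean"].mean(axis=(1, 2, 3))
        slope = np.polyfit(member.years, annual, 1)[0]
        assert slope == pytest.approx(0.05, abs=1e-9)
        # trend persists to the final year
        clim = base.data["tmean"].mean(axis=0).mean()
        assert annual[-1] - clim == pytest.approx(0.5 * (2049 - 1959) / 10, abs=1e-9)

    def test_members_diverge_but_share_longrun_trend(self):
        cfg = _quiet_cfg(
            n_members=3,
            future_years=(1960, 2049),
            interannual_temp_sd_c=0.4,
            scenarios={"rcp85": ScenarioSpec(0.5, 0.05, 0.0, 0.0)},
        )
        dem = synth.make_terrain(cfg)
        base = synth.make_climate(dem, cfg)
        members = synth.make_gcm_ensemble(base, cfg, {"rcp85": cfg.scenarios["rcp85"]})[
            "rcp85"
        ]
        slopes = []
        for m in members:
            annual = m.data["tmean"].mean(axis=(1, 2, 3))
            slopes.append(np.polyfit(m.years, annual, 1)[0] * 10)
        assert not np.allclose(
            members[0].data["tmean"], members[1].data["tmean"]
        ), "members should be distinct trajectories"
        # each member's fitted decadal trend is near the scenario mean:
        # trend spread 0.05 plus AR(1) noise slope error
        assert np.abs(np.array(slopes) - 0.5).max() < 0.25

    def test_unknown_scenario_rejected(self, study):
        with pytest.raises(KeyError):
            synth.make_gcm_ensemble(
                study["climate"], study["cfg"], {"rcp99": ScenarioSpec(1.0)}
            )

    def test_determinism(self, study):
        a = synth.make_gcm_ensemble(study["climate"], study["cfg"])
        b = synth.make_gcm_ensemble(study["climate"], study["cfg"])
        assert np.array_equal(a["rcp85"][0].data["tmean"], b["rcp85"][0].data["tmean"])
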