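"""Synthetic atlas generator: determinism, limits, and statistical structure."""

import numpy as np
import pandas as pd
import pytest

from atlasbias.synthetic import (
    Community,
    ConfigError,
    EffortCoefficients,
    LandscapeConfig,
    generate_checklists,
    generate_community,
    generate_effort,
    generate_landscape,
)


class TestLandscape:
    def test_same_seed_gives_identical_output(self):
        cfg = LandscapeConfig(rows=8, cols=8, seed=3)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        pd.testing.assert_frame_equal(a.covariates.frame, b.covariates.frame)
        assert a.hub_codes == b.hub_codes
        assert np.array_equal(a.road_vertices, b.road_vertices)

    def test_zero_noise_gives_exactly_linear_climate(self):
        land = generate_landscape(LandscapeConfig(rows=10, cols=10, climate_noise=0.0, seed=1))
        precip = land.covariates.frame["precip"].to_numpy().reshape(10, 10)
        # second differences vanish for a linear surface
        assert np.allclose(np.diff(precip, n=2, axis=0), 0.0, atol=1e-9)
        assert np.allclose(np.diff(precip, n=2, axis=1), 0.0, atol=1e-9)
        lo, hi = LandscapeConfig().precip_range
        assert precip[0, 0] == pytest.approx(lo)
        assert precip[-1, -1] == pytest.approx(hi)

    def test_single_hub_distance_is_monotone_away_from_hub(self):
        land = generate_landscape(LandscapeConfig(rows=15, cols=15, n_hubs=1, seed=2))
        d = land.covariates.frame["dist_hub_km"].to_numpy().reshape(15, 15)
        hi, hj = np.unravel_index(np.argmin(d), d.shape)
        row = d[hi, :]
        col = d[:, hj]
        assert np.all(np.diff(row[hj:]) > 0) and np.all(np.diff(row[: hj + 1]) < 0)
        assert np.all(np.diff(col[hi:]) > 0) and np.all(np.diff(col[: hi + 1]) < 0)

    def test_cover_fractions_in_unit_interval(self, small_landscape):
        cov = small_landscape.covariates.frame
        for col in ("protected", "urban", "cultivated"):
            assert cov[col].between(0, 1).all()

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ConfigError):
            generate_landscape(LandscapeConfig(rows=2, cols=10))


class TestEffort:
    def test_intercept_only_mean_matches_rate(self):
        """With all slopes zero the Poisson mean is exp(b0); LLN at n=10,000."""
        land = generate_landscape(LandscapeConfig(rows=100, cols=100, seed=9))
        coeffs = EffortCoefficients(
            b0=np.log(5.0), b_loghub=0, b_road=0, b_prot=0, b_urban=0,
            b_cult=0, b_precip=0, b_tsummer=0, b_twinter=0,
        )
        counts, eta = generate_effort(land, coeffs, seed=4)
        assert np.allclose(eta, np.log(5.0))
        se = np.sqrt(5.0 / len(counts))
        assert counts.mean() == pytest.approx(5.0, abs=3 * se)

    def test_effort_halves_per_efold_of_hub_distance(self):
        """b_loghub = -1: a log-linear Poisson regression of the counts on
        log hub distance recovers unit decay (independent statsmodels fit)."""
        import statsmodels.api as sm

        land = generate_landscape(LandscapeConfig(rows=60, cols=60, seed=10))
        coeffs = EffortCoefficients(
            b0=3.0, b_loghub=-1.0, b_road=0, b_prot=0, b_urban=0,
            b_cult=0, b_precip=0, b_tsummer=0, b_twinter=0,
        )
        counts, _ = generate_effort(land, coeffs, seed=11)
        logd = np.log(land.covariates.frame.loc[counts.index, "dist_hub_km"])
        res = sm.GLM(
            counts.to_numpy(), sm.add_constant(logd.to_numpy()), family=sm.families.Poisson()
        ).fit()
        assert res.params[1] == pytest.approx(-1.0, abs=3 * res.bse[1])

    def test_fixed_seed_reproduces_counts(self, small_landscape):
        a, _ = generate_effort(small_landscape, seed=3)
        b, _ = generate_effort(small_landscape, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_hub_pentads_excluded_from_counts(self, small_landscape):
        counts, _ = generate_effort(small_landscape, seed=3)
        assert not set(small_landscape.hub_codes) & set(counts.index)


def _zones_for(landscape):
    """Trivial two-zone split for community tests."""
    codes = landscape.covariates.frame.index
    half = len(codes) // 2
    return pd.Series(["Z1"] * half + ["Z2"] * (len(codes) - half), index=codes)


class TestCommunity:
    def test_occupancy_one_fills_every_zone_pentad(self, small_landscape):
        zones = _zones_for(small_landscape)
        com = generate_community(
            small_landscape, zones, {"Z1": 40, "Z2": 60}, seed=1, occupancy_prob=1.0
        )
        z1_rows = np.flatnonzero((zones == "Z1").to_numpy())
        assert np.all(com.occupancy[z1_rows].sum(axis=1) == 40)

    def test_full_sharing_with_equal_richness_gives_identical_pools(self, small_landscape):
        zones = _zones_for(small_landscape)
        com = generate_community(
            small_landscape, zones, {"Z1": 30, "Z2": 30}, seed=2,
            occupancy_prob=1.0, shared_fraction=1.0,
        )
        occupied = com.occupancy.any(axis=0)
        assert occupied.sum() == 30  # one pool serves both zones
        assert all(s.startswith("wide") for s, o in zip(com.species, occupied) if o)

    def test_mean_pentad_richness_matches_binomial_mean(self, small_landscape):
        zones = _zones_for(small_landscape)
        com = generate_community(
            small_landscape, zones, {"Z1": 100, "Z2": 100}, seed=3, occupancy_prob=0.3
        )
        per_pentad = com.occupancy.sum(axis=1)
        se = np.sqrt(100 * 0.3 * 0.7 / len(per_pentad))
        assert per_pentad.mean() == pytest.approx(30.0, abs=3 * se)

    def test_heterogeneous_occupancy_keeps_the_mean(self, small_landscape):
        zones = _zones_for(small_landscape)
        com = generate_community(
            small_landscape, zones, {"Z1": 400, "Z2": 400}, seed=4,
            occupancy_prob=0.2, occupancy_alpha=0.35,
        )
        assert com.occupancy_q is not None
        assert com.occupancy_q.mean() == pytest.approx(0.2, abs=0.03)

    def test_invalid_richness_rejected(self, small_landscape):
        with pytest.raises(ConfigError):
            generate_community(small_landscape, _zones_for(small_landscape), {"Z1": 0, "Z2": 5})


class TestChecklists:
    @staticmethod
    def _community(landscape, occupancy_prob=1.0, richness=20, seed=0):
        zones = _zones_for(landscape)
        return generate_community(
            landscape, zones, {"Z1": richness, "Z2": richness},
            seed=seed, occupancy_prob=occupancy_prob,
        )

    def test_perfect_detection_reports_full_occupancy(self, small_landscape):
        com = self._community(small_landscape)
        counts = pd.Series(1, index=com.pentads)
        table, _ = generate_checklists(counts, com, p_det=1.0, seed=5)
        for _, row in table.frame.iterrows():
            i = com.pentads.index(row["pentad"])
            occ = {com.species[j] for j in np.flatnonzero(com.occupancy[i])}
            assert row["species"] == occ

    def test_zero_visits_gives_empty_table(self, small_landscape):
        com = self._community(small_landscape)
        counts = pd.Series(0, index=com.pentads)
        table, truth = generate_checklists(counts, com, p_det=0.9, seed=5)
        assert len(table) == 0
        assert truth.n_empty_lists_dropped == 0

    def test_miss_probability_matches_closed_form(self, small_landscape):
        """P(species never seen in 10 visits | present) = (1-p)^10 = 2^-10."""
        com = self._community(small_landscape, richness=100, seed=6)
        counts = pd.Series(10, index=com.pentads)
        table, _ = generate_checklists(counts, com, p_det=0.5, seed=7)
        seen = {}
        for _, row in table.frame.iterrows():
            seen.setdefault(row["pentad"], set()).update(row["species"])
        trials = misses = 0
        for i, pentad in enumerate(com.pentads):
            occ = {com.species[j] for j in np.flatnonzero(com.occupancy[i])}
            trials += len(occ)
            misses += len(occ - seen.get(pentad, set()))
        p_miss = 2.0 ** -10
        se = np.sqrt(p_miss * (1 - p_miss) / trials)
        assert misses / trials == pytest.approx(p_miss, abs=3 * se + 1e-12)

    def test_detections_subset_of_occupancy(self, small_landscape):
        """No false positives: every listed species occupies its pentad."""
        com = self._community(small_landscape, occupancy_prob=0.4, seed=8)
        counts = pd.Series(3, index=com.pentads)
        table, _ = generate_checklists(counts, com, p_det=0.6, seed=9)
        for _, row in table.frame.iterrows():
            i = com.pentads.index(row["pentad"])
            occ = {com.species[j] for j in np.flatnonzero(com.occupancy[i])}
            assert row["species"] <= occ

    def test_empty_lists_dropped_and_counted(self, small_landscape):
        com = self._community(small_landscape, occupancy_prob=0.05, richness=5, seed=10)
        counts = pd.Series(2, index=com.pentads)
        with pytest.warns(UserWarning, match="empty checklists"):
            table, truth = generate_checklists(counts, com, p_det=0.1, seed=11)
        # visits to pentads with no occupants are also dropped-and-counted
        assert len(table) + truth.n_empty_lists_dropped == int(counts.sum())

    def test_invalid_p_det_rejected(self, small_landscape):
        com = self._community(small_landscape)
        with pytest.raises(ConfigError):
            generate_checklists(pd.Series(1, index=com.pentads), com, p_det=0.0)
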