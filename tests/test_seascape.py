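"""Generator: seascape fields, hurdle truth layers, survey sampling."""

import numpy as np
import pandas as pd
import pytest

import shellbed as sb
from shellbed.seascape import SeascapeConfig, Stratum, SamplingDesign, QUADRAT


class TestGenerateSeascape:
    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            sb.generate_seascape(nrows=0, ncols=5, seed=0)
        with pytest.raises(ValueError):
            sb.Seascape(covariates={"depth": np.zeros((2, 2))}, cell_size=-1)

    def test_single_cell_zero_noise_gives_configured_depth(self):
        sea = sb.generate_seascape(nrows=1, ncols=1, depth_noise=0.0,
                                   depth_range=(2.0, 9.0), seed=0)
        assert sea.covariates["depth"][0, 0] == pytest.approx(2.0)
        for band in sea.covariates.values():
            assert np.isfinite(band).all()

    def test_same_seed_identical(self):
        a = sb.generate_seascape(nrows=30, ncols=30, seed=5)
        b = sb.generate_seascape(nrows=30, ncols=30, seed=5)
        for name in a.names:
            np.testing.assert_array_equal(a.covariates[name], b.covariates[name])

    def test_depth_increases_with_offshore_position(self):
        sea = sb.generate_seascape(nrows=200, ncols=200, seed=3)
        m = sea.mask
        r = np.corrcoef(sea.covariates["depth"][m], sea.covariates["X"][m])[0, 1]
        assert r > 0

    def test_substrate_proportions_valid(self, small_seascape):
        h = small_seascape.covariates["P_HARD"]
        s = small_seascape.covariates["P_SOFT"]
        assert ((h >= 0) & (h <= 1)).all() and ((s >= 0) & (s <= 1)).all()
        assert (h + s <= 1 + 1e-12).all()

    def test_mask_is_zero_to_ten_metres(self, small_seascape):
        d = small_seascape.covariates["depth"][small_seascape.mask]
        assert d.min() >= 0 and d.max() <= 10


class TestGenerateTruth:
    def test_intercept_zero_gives_half_probability(self, small_seascape):
        params = sb.HurdleParams(occ_coefs={"intercept": 0.0},
                                 abund_coefs={"intercept": 0.0}, sigma=0.0)
        truth = sb.generate_truth(small_seascape, params, seed=0)
        m = small_seascape.mask
        assert truth.p[m].mean() == pytest.approx(0.5)

    def test_zero_sigma_density_is_exactly_exponential_of_predictor(self, small_seascape):
        params = sb.HurdleParams(occ_coefs={"intercept": 10.0},  # ~always present
                                 abund_coefs={"intercept": 1.0, "depth": 0.2},
                                 sigma=0.0)
        truth = sb.generate_truth(small_seascape, params, seed=1)
        m = small_seascape.mask & (truth.occurrence == 1)
        expected = np.exp(1.0 + 0.2 * small_seascape.covariates["depth"][m])
        np.testing.assert_allclose(truth.realized_density[m], expected)

    def test_negative_depth_coefficient_shifts_probability_shallow(self, small_seascape):
        params = sb.HurdleParams(occ_coefs={"intercept": 1.0, "depth": -0.8},
                                 abund_coefs={"intercept": 0.0})
        truth = sb.generate_truth(small_seascape, params, seed=2)
        m = small_seascape.mask
        d = small_seascape.covariates["depth"]
        med = np.median(d[m])
        assert truth.p[m & (d > med)].mean() < truth.p[m & (d <= med)].mean()

    def test_absent_cells_have_zero_density(self, small_seascape, species_truths):
        for truth in species_truths.values():
            assert (truth.realized_density[truth.occurrence == 0] == 0).all()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            sb.HurdleParams(occ_coefs={}, abund_coefs={}, sigma=-0.1)


class TestSampleSites:
    def test_site_counts_and_labels_per_stratum(self, small_seascape, species_truths):
        strata = [Stratum(depth=(lo, hi), n_sites=10, method=QUADRAT)
                  for lo, hi in [(0, 1), (1, 2), (2, 5), (5, 10)]]
        for s in strata:
            s.method = sb.TOW if s.depth[0] >= 0.5 else QUADRAT
        design = SamplingDesign(strata=strata, seed=1)
        table = sb.sample_sites(small_seascape, species_truths, design)
        assert len(table) == 40
        assert table.groupby("stratum").size().eq(10).all()

    def test_tow_sampled_area_is_sixteen_m2(self, survey):
        assert (survey.loc[survey["method"] == "tow", "area"] == 16.0).all()

    def test_density_times_area_reproduces_count(self, survey):
        for sp in ("mytilus", "magallana", "ostrea"):
            np.testing.assert_allclose(
                survey[f"density_{sp}"] * survey["area"], survey[f"count_{sp}"])

    def test_poisson_observation_mean(self, small_seascape):
        # constant truth: density 4 everywhere; 1 m^2 quadrats
        ones = np.ones(small_seascape.shape)
        truth = sb.HurdleTruth(p=ones, occurrence=ones.astype(int),
                               expected_density=4 * ones,
                               realized_density=4 * ones,
                               cell_area=small_seascape.cell_area)
        quad = sb.ObservationMethod("quadrat", area=1.0, depth_max=10.0)
        design = SamplingDesign(
            strata=[Stratum(depth=(0.0, 10.0), n_sites=10_000, method=quad)],
            seed=2)
        table = sb.sample_sites(small_seascape, {"sp": truth}, design)
        se = np.sqrt(4.0 / len(table))
        assert abs(table["count_sp"].mean() - 4.0) < 3 * se

    def test_same_seed_bit_identical_survey(self, small_seascape, species_truths):
        d1 = sb.default_design(n_sites=100, seed=9, seascape=small_seascape)
        d2 = sb.default_design(n_sites=100, seed=9, seascape=small_seascape)
        t1 = sb.sample_sites(small_seascape, species_truths, d1)
        t2 = sb.sample_sites(small_seascape, species_truths, d2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_stratum_warns_and_skips(self, small_seascape, species_truths):
        deep = Stratum(depth=(9.99, 10.0), n_sites=5, method=sb.TOW)
        sea = sb.generate_seascape(nrows=10, ncols=10, seed=0,
                                   depth_range=(1.0, 5.0), depth_noise=0.0)
        design = SamplingDesign(strata=[deep], seed=0)
        truth = sb.generate_truth(sea, sb.HurdleParams(
            occ_coefs={"intercept": 0}, abund_coefs={"intercept": 0}), seed=0)
        with pytest.warns(UserWarning, match="empty"):
            table = sb.sample_sites(sea, {"sp": truth}, design)
        assert len(table) == 0


class TestTruePopulation:
    def test_zero_density_gives_zero(self, small_seascape):
        z = np.zeros(small_seascape.shape)
        truth = sb.HurdleTruth(p=z, occurrence=z.astype(int), expected_density=z,
                               realized_density=z, cell_area=100.0)
        assert sb.true_population(truth) == 0.0

    def test_uniform_density_closed_form(self):
        ones = np.ones((10, 10))
        truth = sb.HurdleTruth(p=ones, occurrence=ones.astype(int),
                               expected_density=ones, realized_density=ones,
                               cell_area=100.0)
        assert sb.true_population(truth) == pytest.approx(10_000.0)

    def test_matches_naive_cell_loop(self, species_truths):
        truth = species_truths["mytilus"]
        total = 0.0
        nr, nc = truth.realized_density.shape
        for i in range(nr):
            for j in range(nc):
                total += truth.realized_density[i, j] * truth.cell_area
        assert sb.true_population(truth) == pytest.approx(total)

    def test_conserved_over_zone_stratum_partition(self, small_seascape, species_truths):
        truth = species_truths["magallana"]
        strat = sb.build_stratification(small_seascape)
        total = 0.0
        for z, s in strat.areas.index:
            sel = (strat.zone_of == z) & (strat.stratum_of == s)
            total += truth.realized_density[sel].sum() * truth.cell_area
        assert total == pytest.approx(sb.true_population(truth), rel=1e-12)
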