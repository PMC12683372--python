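"""Depth/exposure summaries, overlap tables, central ranges, importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingRegressor

import shellbed as sb


class TestSubsampleCells:
    def test_full_mask_when_n_equals_mask(self, small_seascape):
        n = int(small_seascape.mask.sum())
        cells = sb.subsample_cells(small_seascape, {}, n=n, seed=0)
        assert len(cells) == n

    def test_oversized_request_warns_and_returns_all(self, small_seascape):
        n = int(small_seascape.mask.sum())
        with pytest.warns(UserWarning):
            cells = sb.subsample_cells(small_seascape, {}, n=n + 10, seed=0)
        assert len(cells) == n

    def test_same_seed_identical_sample(self, small_seascape):
        a = sb.subsample_cells(small_seascape, {}, n=500, seed=3)
        b = sb.subsample_cells(small_seascape, {}, n=500, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_is_representative_of_mask(self, small_seascape):
        # mean shallow-fraction over repeated draws approaches the full-mask
        # fraction within 3 SE of the hypergeometric/binomial scale
        full = small_seascape.covariates["depth"][small_seascape.mask]
        p = np.mean(full < 5.0)
        n = 400
        fracs = [np.mean(sb.subsample_cells(small_seascape, {}, n=n,
                                            seed=s)["depth"] < 5.0)
                 for s in range(30)]
        se = np.sqrt(p * (1 - p) / n) / np.sqrt(30)
        assert abs(np.mean(fracs) - p) < 3 * se

    def test_misaligned_layer_rejected(self, small_seascape):
        with pytest.raises(ValueError, match="misaligned"):
            sb.subsample_cells(small_seascape, {"x": np.ones((2, 2))}, n=10)


class TestStratify:
    def _cells(self):
        # 12 hand-built cells across 2 depth bins and both exposure classes
        return pd.DataFrame({
            "depth": [0.1, 0.2, 0.3, 0.4, 0.7, 0.8, 0.6, 0.9, 0.2, 0.3, 0.7, 0.6],
            "exposure": [1e3] * 4 + [1e3] * 4 + [1e5] * 4,
            "presence_sp": [1, 1, 0, 0, 1, 0, 0, 0, 1, 1, 1, 0],
            "density_sp": [4.0, 2.0, 0, 0, 1.0, 0, 0, 0, 2.0, 1.0, 2.0, 0],
        })

    def test_hand_tabulated_bins(self):
        out = sb.stratify(self._cells(), ["sp"])
        out = out.set_index(["depth_bin", "exposure_class"])

        def row(lo, cls):
            bins = out.index.get_level_values(0)
            sel = [b.left == lo for b in bins]
            sub = out[sel]
            return sub.xs(cls, level=1).iloc[0]

        shallow_shel = row(0.0, "sheltered")
        assert shallow_shel["available"] == 4
        assert shallow_shel["occupancy_sp"] == pytest.approx(0.5)
        assert shallow_shel["mean_density_sp"] == pytest.approx(1.5)
        assert shallow_shel["share_sp"] == pytest.approx(6.0 / 12.0)
        deep_exp = row(0.5, "exposed")
        assert deep_exp["available"] == 2
        assert deep_exp["share_sp"] == pytest.approx(2.0 / 12.0)

    def test_full_occupancy_everywhere(self):
        cells = self._cells()
        cells["presence_sp"] = 1
        out = sb.stratify(cells, ["sp"])
        occ = out.loc[out["available"] > 0, "occupancy_sp"]
        assert (occ == 1.0).all()

    def test_shares_sum_to_one(self):
        out = sb.stratify(self._cells(), ["sp"])
        assert out["share_sp"].sum() == pytest.approx(1.0)

    def test_share_times_total_conserves_total(self):
        cells = self._cells()
        out = sb.stratify(cells, ["sp"])
        total = cells["density_sp"].sum()
        assert (out["share_sp"] * total).sum() == pytest.approx(total)


class TestOverlapTable:
    def test_disjoint_layers_no_pairs(self):
        mask = np.ones((1, 9), bool)
        a = np.zeros((1, 9), bool); a[0, :3] = True
        b = np.zeros((1, 9), bool); b[0, 3:6] = True
        c = np.zeros((1, 9), bool); c[0, 6:8] = True
        tab = sb.overlap_table({"a": a, "b": b, "c": c}, mask)
        combos = tab.set_index("combination")["percent"]
        for pair in ("a+b", "a+c", "b+c", "a+b+c"):
            assert combos[pair] == 0.0

    def test_identical_layers_only_all_or_none(self):
        mask = np.ones((2, 5), bool)
        lay = np.zeros((2, 5), bool); lay[0] = True
        tab = sb.overlap_table({"a": lay, "b": lay, "c": lay}, mask)
        combos = tab.set_index("combination")["percent"]
        assert combos["none"] == 50.0
        assert combos["a+b+c"] == 50.0
        assert combos.drop(["none", "a+b+c"]).eq(0).all()

    def test_ten_cell_full_enumeration(self):
        mask = np.ones((1, 10), bool)
        A = np.zeros((1, 10), bool); A[0, 0:4] = True   # cells 1-4
        B = np.zeros((1, 10), bool); B[0, 2:6] = True   # cells 3-6
        C = np.zeros((1, 10), bool); C[0, 6] = True     # cell 7
        tab = sb.overlap_table({"A": A, "B": B, "C": C}, mask)
        combos = tab.set_index("combination")["percent"]
        assert combos["none"] == pytest.approx(30.0)
        assert combos["A"] == pytest.approx(20.0)
        assert combos["A+B"] == pytest.approx(20.0)
        assert combos["B"] == pytest.approx(20.0)
        assert combos["C"] == pytest.approx(10.0)
        summ = tab.attrs["species_summary"]
        assert summ["A"]["T"] == pytest.approx(40.0)
        assert summ["B"]["T"] == pytest.approx(40.0)
        assert summ["C"]["T"] == pytest.approx(10.0)

    def test_percentages_sum_to_hundred(self, rng):
        mask = rng.random((20, 20)) < 0.7
        layers = {k: (rng.random((20, 20)) < 0.3) for k in "abc"}
        tab = sb.overlap_table(layers, mask)
        assert tab["percent"].sum() == pytest.approx(100.0)

    def test_misaligned_layers_rejected(self):
        with pytest.raises(ValueError):
            sb.overlap_table({"a": np.ones((2, 2), bool)}, np.ones((3, 3), bool))


class TestCentralRange:
    def test_point_mass_single_bin(self):
        shares = pd.Series([1.0, 0.0, 0.0], index=[0.0, 0.5, 1.0])
        assert sb.central_range(shares) == (0.0, 0.5)

    def test_uniform_shares_shallow_tiebreak(self):
        shares = pd.Series(np.full(20, 0.05), index=np.arange(0, 10, 0.5))
        assert sb.central_range(shares, 0.80) == (0.0, 8.0)

    def test_exhaustive_window_example(self):
        shares = pd.Series([0.5, 0.3, 0.2], index=[0.0, 0.5, 1.0])
        assert sb.central_range(shares, 0.80) == (0.0, 1.0)

    def test_monotone_in_mass(self, rng):
        v = rng.random(20)
        shares = pd.Series(v / v.sum(), index=np.arange(0, 10, 0.5))
        widths = [sb.central_range(shares, m)[1] - sb.central_range(shares, m)[0]
                  for m in (0.5, 0.7, 0.9)]
        assert widths == sorted(widths)

    def test_invalid_mass_rejected(self):
        shares = pd.Series([1.0], index=[0.0])
        with pytest.raises(ValueError):
            sb.central_range(shares, 0.0)


class TestImportanceAndPartials:
    def test_single_variable_model_scores_hundred(self, rng):
        x = rng.uniform(0, 1, 300)
        df = pd.DataFrame({"x": x})
        model = GradientBoostingRegressor(random_state=0).fit(df, 2 * x)
        imp, _ = sb.importance_and_partials(model, df, ["x"])
        assert imp["x"] == 100.0

    def test_noise_variable_scores_low(self, rng):
        n = 500
        df = pd.DataFrame({"x": rng.uniform(0, 1, n),
                           "noise": rng.uniform(0, 1, n)})
        y = 3 * df["x"] + 0.05 * rng.normal(size=n)
        model = GradientBoostingRegressor(random_state=0).fit(df, y)
        imp, _ = sb.importance_and_partials(model, df, ["x", "noise"])
        assert imp["x"] == 100.0
        assert imp["noise"] < 10.0

    def test_partial_dependence_recovers_univariate_function(self, rng):
        x = rng.uniform(0, 1, 600)
        df = pd.DataFrame({"x": x})
        model = GradientBoostingRegressor(n_estimators=300, random_state=0)
        model.fit(df, 2.0 * x)
        _, partials = sb.importance_and_partials(model, df, ["x"],
                                                 grid_resolution=9)
        curve = partials["x"]
        inner = curve[(curve["x"] > 0.1) & (curve["x"] < 0.9)]
        np.testing.assert_allclose(inner["partial_dependence"],
                                   2.0 * inner["x"], atol=0.1)
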