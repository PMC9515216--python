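"""ARDA aggregation, thresholding, quantification, band, rendering."""

import numpy as np
import pandas as pd
import pytest

from ardaceph.arda import (ARDA_CMAP, ArdaMap, arda_surface, build_arda,
                           instance_stats, normal_band, quantify_instances,
                           render_arda, significant_region)
from ardaceph.core import AgedImage
from ardaceph.saliency import SalienceMap


def _maps(n, age, shape=(8, 8), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        v = rng.random(shape)
        out.append(SalienceMap(values=v / v.max(), age=age, normalized=True))
    return out


class TestBuildArda:
    def test_single_subject_is_identity(self):
        (m,) = _maps(1, 20)
        (a,) = build_arda([m])
        assert np.array_equal(a.values, m.values)
        assert a.age == 20 and a.n_subjects == 1

    def test_mean_is_idempotent_on_identical_maps(self):
        m = _maps(1, 9)[0]
        twin = SalienceMap(values=m.values.copy(), age=9, normalized=True)
        (a,) = build_arda([m, twin])
        assert np.allclose(a.values, m.values)

    def test_matches_accumulate_divide_loop(self):
        maps = _maps(50, 15, seed=3)
        (a,) = build_arda(maps)
        acc = np.zeros((8, 8))
        for m in maps:
            acc += m.values
        assert np.allclose(a.values, acc / 50, atol=1e-12)

    def test_ages_bin_by_completed_years(self):
        maps = [SalienceMap(values=np.ones((4, 4)), age=age) for age in (20.1, 20.9, 21.0)]
        out = build_arda(maps)
        assert [(a.age, a.n_subjects) for a in out] == [(20, 2), (21, 1)]

    def test_mixed_grids_rejected(self):
        a = SalienceMap(values=np.ones((4, 4)), age=10)
        b = SalienceMap(values=np.ones((8, 8)), age=10)
        with pytest.raises(ValueError):
            build_arda([a, b])

    def test_mean_bounded_by_contributors(self):
        maps = _maps(10, 12, seed=5)
        (a,) = build_arda(maps)
        stack = np.stack([m.values for m in maps])
        assert np.all(a.values >= stack.min(axis=0) - 1e-12)
        assert np.all(a.values <= stack.max(axis=0) + 1e-12)


class TestSignificantRegion:
    def test_constant_map_fully_significant(self):
        a = ArdaMap(values=np.full((6, 6), 0.3), age=10, n_subjects=2)
        for level in ("median", "p75", "p90"):
            r = significant_region(a, level)
            assert r.threshold_value == pytest.approx(0.3)
            assert r.mask.all()

    def test_p90_keeps_top_decile(self):
        vals = np.arange(1, 101, dtype=float).reshape(10, 10)
        r = significant_region(ArdaMap(values=vals, age=10, n_subjects=1), "p90")
        assert r.mask.sum() == np.sum(vals >= np.percentile(vals, 90))
        assert 9 <= r.mask.sum() <= 11

    def test_median_on_two_valued_map(self):
        vals = np.concatenate([np.zeros(50), np.ones(50)]).reshape(10, 10)
        r = significant_region(ArdaMap(values=vals, age=10, n_subjects=1), "median")
        assert r.mask.sum() == np.sum(vals >= r.threshold_value)

    def test_masks_nest_across_levels(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = ArdaMap(values=rng.random((12, 12)), age=10, n_subjects=1)
            med = significant_region(a, "median").mask
            p75 = significant_region(a, "p75").mask
            p90 = significant_region(a, "p90").mask
            assert np.all(p90 <= p75) and np.all(p75 <= med)

    def test_unknown_level_rejected(self):
        a = ArdaMap(values=np.ones((4, 4)), age=10, n_subjects=1)
        with pytest.raises(ValueError):
            significant_region(a, "p42")


class TestQuantifyInstances:
    def _arda(self, vals):
        return ArdaMap(values=vals, age=20, n_subjects=3)

    def test_instance_inside_region_on_constant_map(self):
        vals = np.full((8, 8), 0.25)
        labels = np.zeros((8, 8), int)
        labels[2:5, 2:5] = 1
        region = significant_region(self._arda(vals), "median")
        q = quantify_instances(self._arda(vals), region, labels, {1: "blob"})
        assert q.loc[0, "value"] == pytest.approx(0.25)
        assert q.loc[0, "instance"] == "blob"

    def test_disjoint_instance_is_missing_not_zero(self):
        vals = np.zeros((8, 8))
        vals[:4] = 1.0
        labels = np.zeros((8, 8), int)
        labels[6:, 6:] = 1
        region = significant_region(self._arda(vals), "p75")
        q = quantify_instances(self._arda(vals), region, labels)
        assert np.isnan(q.loc[0, "value"]) and q.loc[0, "n_pixels"] == 0

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(9)
        vals = rng.random((10, 10))
        labels = rng.integers(0, 3, (10, 10))
        arda = self._arda(vals)
        region = significant_region(arda, "p75")
        q = quantify_instances(arda, region, labels).set_index("instance")
        for lbl in (1, 2):
            picked = [
                vals[i, j]
                for i in range(10)
                for j in range(10)
                if labels[i, j] == lbl and region.mask[i, j]
            ]
            expected = np.mean(picked) if picked else np.nan
            got = q.loc[str(lbl), "value"]
            assert got == pytest.approx(expected) or (np.isnan(got) and picked == [])

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(10)
        vals = rng.random((10, 10))
        labels = rng.integers(0, 3, (10, 10))
        arda = self._arda(vals)
        region = significant_region(arda, "median")
        a = quantify_instances(arda, region, labels, {1: "x", 2: "y"})
        swapped = np.where(labels == 1, 2, np.where(labels == 2, 1, 0))
        b = quantify_instances(arda, region, swapped, {2: "x", 1: "y"})
        merged = a.merge(b, on="instance", suffixes=("_a", "_b"))
        assert np.allclose(merged["value_a"], merged["value_b"], equal_nan=True)

    def test_misaligned_labels_rejected(self):
        arda = self._arda(np.ones((8, 8)))
        region = significant_region(arda, "median")
        with pytest.raises(ValueError):
            quantify_instances(arda, region, np.zeros((4, 4), int))


class TestSurfaceAndStats:
    def test_surface_cardinality_and_order(self):
        rows = [
            {"age": a, "instance": i, "level": lv, "value": 0.1, "n_pixels": 5}
            for a in (5, 6)
            for i in ("b", "a", "c")
            for lv in ("p90", "median", "p75")
        ]
        surf = arda_surface(pd.DataFrame(rows), instance_order=["a", "b", "c"])
        assert len(surf) == 18
        assert list(surf["age"].unique()) == [5, 6]
        assert list(surf.loc[surf["age"] == 5, "instance"].unique()) == ["a", "b", "c"]
        assert list(surf["level"].iloc[:3]) == ["median", "p75", "p90"]

    def test_missing_cells_stay_missing(self):
        df = pd.DataFrame(
            [{"age": 5, "instance": "a", "level": "p75", "value": np.nan, "n_pixels": 0}]
        )
        surf = arda_surface(df)
        assert np.isnan(surf["value"].iloc[0])

    def test_instance_stats_mu_sigma(self):
        df = pd.DataFrame(
            {"instance": ["a"] * 4, "age": [20] * 4, "value": [0.1, 0.2, 0.3, 0.4]}
        )
        out = instance_stats(df)
        assert out.loc[0, "mu"] == pytest.approx(0.25)
        assert out.loc[0, "sigma"] == pytest.approx(np.std([0.1, 0.2, 0.3, 0.4]))


class TestNormalBand:
    def test_reference_worked_example(self):
        low, high, cov = normal_band(0.089, 0.015, 2.0)
        assert low == pytest.approx(0.059)
        assert high == pytest.approx(0.119)
        assert cov == 95.45

    def test_one_sigma_coverage(self):
        assert normal_band(0.0, 1.0, 1.0)[2] == 68.27

    def test_degenerate_sigma(self):
        low, high, cov = normal_band(0.5, 0.0, 2.0)
        assert low == high == 0.5 and cov == 95.45

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            normal_band(0.1, -0.01)


class TestRenderArda:
    def _base(self, shape=(8, 8)):
        return AgedImage(id="b", pixels=np.zeros(shape), age=20.0)

    def test_colormap_endpoints(self):
        assert ARDA_CMAP(0.0)[:3] == pytest.approx((0.0, 0.0, 1.0))
        assert ARDA_CMAP(1.0)[:3] == pytest.approx((1.0, 0.0, 0.0))

    def test_zero_map_renders_blue_tint(self):
        a = ArdaMap(values=np.zeros((8, 8)), age=10, n_subjects=1)
        rgb = render_arda(a, self._base(), alpha=1.0)
        assert np.allclose(rgb[..., 2], 1.0) and np.allclose(rgb[..., 0], 0.0)

    def test_alpha_zero_keeps_base(self):
        rng = np.random.default_rng(0)
        base = AgedImage(id="b", pixels=rng.random((8, 8)), age=20.0)
        a = ArdaMap(values=rng.random((8, 8)), age=10, n_subjects=1)
        rgb = render_arda(a, base, alpha=0.0)
        assert np.allclose(rgb, np.repeat(base.pixels[..., None], 3, axis=2))

    def test_grid_mismatch_rejected(self):
        a = ArdaMap(values=np.zeros((8, 8)), age=10, n_subjects=1)
        with pytest.raises(ValueError):
            render_arda(a, self._base((4, 4)))
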