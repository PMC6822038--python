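"""Backgrounds, environmental PCA, occupancy grids, Schoener's D,
equivalency test."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloniche import overlap as ov
from phyloniche.core_io import ClimateRaster
from phyloniche.overlap import (EnvBackground, build_background,
                                equivalency_test, host_union, occupancy_grid,
                                pca_env, schoener_d)
from phyloniche.synth import make_pair_scenario, make_synthetic_rasters


class TestHostUnion:
    assoc = {"bug": {"H1", "H2"}, "group": {"H1", "H2", "H3"}}

    def test_union_counts(self):
        host_occ = pd.DataFrame({
            "species": ["H1"] * 3 + ["H2"] * 4,
            "lon": np.arange(7.0), "lat": np.arange(7.0)})
        out = host_union("bug", self.assoc, host_occ)
        assert len(out) == 7
        assert set(out["species"]) == {"hosts_of_bug"}

    def test_shared_coordinate_kept_once(self):
        host_occ = pd.DataFrame({"species": ["H1", "H2"],
                                 "lon": [1.0, 1.0], "lat": [2.0, 2.0]})
        assert len(host_union("bug", self.assoc, host_occ)) == 1

    def test_group_entity_unions_all_members_hosts(self):
        host_occ = pd.DataFrame({"species": ["H1", "H2", "H3"],
                                 "lon": [1.0, 2.0, 3.0],
                                 "lat": [1.0, 2.0, 3.0]})
        out = host_union("group", self.assoc, host_occ)
        assert len(out) == 3

    def test_no_records_at_all_is_error(self):
        host_occ = pd.DataFrame({"species": ["other"], "lon": [0.0],
                                 "lat": [0.0]})
        with pytest.raises(ValueError, match="no host"):
            host_union("bug", self.assoc, host_occ)


class TestBackground:
    @staticmethod
    def _rasters():
        return make_synthetic_rasters(extent=(-20.0, 20.0, 40.0, 60.0),
                                      resolution=1.0, seed=1)

    def test_buffer_rule(self):
        occ = pd.DataFrame({"species": "s", "lon": [10.0, 20.0],
                            "lat": [40.0, 45.0]})
        big = make_synthetic_rasters(extent=(-30.0, 0.0, 60.0, 80.0),
                                     resolution=1.0, seed=1)
        bg = build_background(occ, big, buffer=10.0)
        assert bg.rectangle == (0.0, 30.0, 30.0, 55.0)

    def test_zero_buffer_is_bounding_box(self):
        occ = pd.DataFrame({"species": "s", "lon": [-5.0, 5.0],
                            "lat": [45.0, 55.0]})
        bg = build_background(occ, self._rasters(), buffer=0.0)
        assert bg.rectangle == (-5.0, 45.0, 5.0, 55.0)

    def test_clipped_to_raster_and_pole(self):
        occ = pd.DataFrame({"species": "s", "lon": [0.0], "lat": [58.0]})
        rasters = make_synthetic_rasters(extent=(-10.0, 40.0, 10.0, 90.0),
                                         resolution=1.0, seed=1)
        bg = build_background(occ, rasters, buffer=40.0)
        assert bg.rectangle == (-10.0, 40.0, 10.0, 90.0)

    def test_nodata_cells_excluded(self):
        rasters = make_synthetic_rasters(extent=(-20.0, 40.0, 20.0, 60.0),
                                         resolution=1.0, nodata_border=2,
                                         seed=1)
        occ = pd.DataFrame({"species": "s", "lon": [0.0], "lat": [50.0]})
        bg = build_background(occ, rasters, buffer=100.0)
        assert len(bg.pixel_scores) == (40 - 4) * (20 - 4)


class TestPcaEnv:
    def test_collinear_pixels_one_axis(self):
        t = np.linspace(0, 1, 50)
        pix = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        bg = EnvBackground((0, 0, 1, 1), pix)
        space = pca_env(bg, bg)
        assert space.explained_variance_ratio[0] == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_duplicated_set_same_axes(self):
        rng = np.random.default_rng(2)
        pix = pd.DataFrame(rng.normal(size=(200, 5)),
                           columns=list("abcde"))
        bg = EnvBackground((0, 0, 1, 1), pix)
        both = pca_env(bg, bg)
        single = pca_env(bg, EnvBackground((0, 0, 1, 1), pix.iloc[:0]))
        np.testing.assert_allclose(np.abs(both.loadings),
                                   np.abs(single.loadings), atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        pix = pd.DataFrame(rng.normal(size=(500, 5)) @ np.diag([3, 2, 1, 1, 1]),
                           columns=list("abcde"))
        bg = EnvBackground((0, 0, 1, 1), pix)
        space = pca_env(bg, bg)
        Z = (pix.to_numpy() - space.center) / space.scale
        Zp = np.vstack([Z, Z])  # pooled = duplicated set
        w = np.linalg.eigvalsh(np.cov(Zp.T))[::-1]
        ratio = w / w.sum()
        np.testing.assert_allclose(space.explained_variance_ratio,
                                   ratio[:2], atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        pix = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        bg = EnvBackground((0, 0, 1, 1), pix)
        space = pca_env(bg, bg)
        np.testing.assert_allclose(space.loadings @ space.loadings.T,
                                   np.eye(2), atol=1e-10)


class TestOccupancyGrid:
    def test_z_sums_to_one(self):
        rng = np.random.default_rng(5)
        occ = rng.normal(size=(40, 2))
        bg = rng.normal(size=(2000, 2)) * 2.0
        ext = (-6.0, 6.0, -6.0, 6.0)
        grid = occupancy_grid(occ, bg, ext, R=50)
        assert grid.z.sum() == pytest.approx(1.0, abs=1e-9)
        assert grid.o.min() >= 0 and grid.e.min() >= 0

    def test_corner_cluster_locates_argmax(self):
        rng = np.random.default_rng(6)
        occ = np.array([[-4.0, -4.0]]) + 0.05 * rng.normal(size=(30, 2))
        bg = rng.uniform(-5, 5, size=(4000, 2))
        grid = occupancy_grid(occ, bg, (-5.0, 5.0, -5.0, 5.0), R=50)
        iy, ix = np.unravel_index(np.argmax(grid.z), grid.z.shape)
        assert ix < 10 and iy < 10  # the low-x, low-y corner region

    def test_self_consistency_of_correction(self):
        """Occurrences drawn from the availability distribution itself give
        near-uniform corrected occupancy over well-available cells."""
        rng = np.random.default_rng(7)
        bg = rng.normal(size=(5000, 2))
        occ = rng.normal(size=(5000, 2))
        grid = occupancy_grid(occ, bg, (-4.0, 4.0, -4.0, 4.0), R=40)
        core = grid.e > 0.25 * grid.e.max()
        z_core = grid.z[core]
        assert z_core.max() / z_core.min() < 2.0

    def test_identical_scores_zero_bandwidth_error(self):
        occ = np.ones((6, 2))
        bg = np.random.default_rng(8).normal(size=(100, 2))
        with pytest.raises(ValueError, match="bandwidth"):
            occupancy_grid(occ, bg, (-3, 3, -3, 3), R=20)


class TestSchoenerD:
    def test_identical_grids_give_one(self):
        z = np.random.default_rng(9).dirichlet(np.ones(100)).reshape(10, 10)
        assert schoener_d(z, z) == 1.0

    def test_disjoint_supports_give_zero(self):
        za = np.zeros(10); za[:5] = 0.2
        zb = np.zeros(10); zb[5:] = 0.2
        assert schoener_d(za, zb) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        za = np.array([0.6, 0.4, 0.0, 0.0])
        zb = np.array([0.4, 0.6, 0.0, 0.0])
        assert schoener_d(za, zb) == pytest.approx(0.8, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            schoener_d(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_symmetry_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        za = rng.dirichlet(np.ones(30))
        zb = rng.dirichlet(np.ones(30))
        d = schoener_d(za, zb)
        assert schoener_d(zb, za) == d
        perm = rng.permutation(30)
        assert schoener_d(za[perm], zb[perm]) == pytest.approx(d, abs=1e-12)
        assert 0.0 <= d <= 1.0


class TestEquivalency:
    def test_same_points_give_d_one_p_one(self):
        ins, _, rasters, _ = make_pair_scenario("equivalent", seed=0)
        res = equivalency_test(ins, ins.copy(), rasters, reps=30, seed=1)
        assert res.d_obs == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_determinism_including_null_order(self):
        ins, host, rasters, _ = make_pair_scenario("truncated", seed=4)
        a = equivalency_test(ins, host, rasters, reps=25, seed=9)
        b = equivalency_test(ins, host, rasters, reps=25, seed=9)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())

    def test_p_lower_bound(self):
        res = ov.EquivalencyResult(d_obs=0.1, null_d=[0.5] * 99, n_reps=99,
                                   p_value=(0 + 1) / 100, seed=0)
        assert res.p_value == 1.0 / (res.n_reps + 1)

    def test_truncated_scenario_rejects(self):
        ins, host, rasters, _ = make_pair_scenario("truncated", seed=2)
        res = equivalency_test(ins, host, rasters, reps=100, seed=3)
        assert res.p_value <= 0.05

    def test_too_few_records_rejected(self):
        ins, host, rasters, _ = make_pair_scenario("equivalent", seed=0)
        with pytest.raises(ValueError, match=">= 5"):
            equivalency_test(ins.head(3), host, rasters, reps=10, seed=1)
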