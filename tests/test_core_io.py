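"""Trees, occurrence tables and rasters: parsing, invariants, round trips."""

import numpy as np
import pandas as pd
import pytest

from phyloniche import core_io
from phyloniche.core_io import (ClimateRaster, RasterError, TreeError,
                                apply_species_groups, filter_min_occurrences,
                                read_occurrences, read_raster, read_tree,
                                write_raster)
from phyloniche.signal import tree_vcv
from phyloniche.synth import simulate_yule_tree

from conftest import tree_of


class TestReadTree:
    def test_two_tip_depths(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1):0;\n")
        tree = read_tree(p)
        assert tree.n_tips == 2
        assert tree.tip_depths() == {"A": 1.0, "B": 1.0}
        assert tree.is_ultrametric

    def test_three_tip_ultrametric(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2):0;\n")
        tree = read_tree(p)
        assert all(d == pytest.approx(2.0) for d in tree.tip_depths().values())
        assert tree.is_ultrametric

    def test_non_ultrametric_flagged_not_fatal(self, tmp_path, caplog):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:2):1,C:2):0;\n")
        with caplog.at_level("WARNING", logger="phyloniche"):
            tree = read_tree(p)
        assert not tree.is_ultrametric
        assert any("ultrametric" in r.message for r in caplog.records)

    def test_malformed_newick_raises(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1:1,C:2);\n")
        with pytest.raises(TreeError, match="malformed"):
            read_tree(p)

    def test_duplicate_tips_rejected(self, tmp_path):
        p = tmp_path / "dup.nwk"
        p.write_text("((A:1,A:1):1,C:2):0;\n")
        with pytest.raises(TreeError, match="duplicate"):
            read_tree(p)

    def test_negative_branch_rejected(self):
        with pytest.raises(TreeError, match="negative"):
            tree_of("((A:1,B:-1):1,C:2):0;")


class TestReadOccurrences:
    def test_duplicates_removed(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,lon,lat\nx,1.0,2.0\nx,1.0,2.0\ny,3.0,4.0\n")
        assert len(read_occurrences(p)) == 2

    def test_out_of_bounds_latitude_rejected(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,lon,lat\nx,1.0,95.0\ny,3.0,4.0\n")
        out = read_occurrences(p)
        assert list(out["species"]) == ["y"]

    def test_empty_file_with_header(self, tmp_path, caplog):
        p = tmp_path / "o.csv"
        p.write_text("species,lon,lat\n")
        with caplog.at_level("WARNING", logger="phyloniche"):
            out = read_occurrences(p)
        assert out.empty

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,x,y\na,1,2\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_occurrences(p)

    def test_unparseable_coordinate_rejected(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,lon,lat\nx,east,2.0\ny,3.0,4.0\n")
        assert list(read_occurrences(p)["species"]) == ["y"]

    def test_extra_columns_preserved(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,lon,lat,source\nx,1.0,2.0,GBIF\n")
        assert read_occurrences(p)["source"].iloc[0] == "GBIF"


class TestRasters:
    def test_ascii_header_arithmetic(self, tmp_path):
        p = tmp_path / "g.asc"
        body = "\n".join(" ".join("1" for _ in range(10)) for _ in range(10))
        p.write_text("ncols 10\nnrows 10\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1.0\nNODATA_value -9999\n" + body + "\n")
        r = read_raster(p)
        assert r.extent == (0.0, 0.0, 10.0, 10.0)
        assert r.shape == (10, 10)

    def test_nodata_cells_masked(self, tmp_path):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        vals[0, 0] = vals[1, 2] = vals[3, 3] = -9999.0
        r = ClimateRaster(vals, (0, 0, 4, 4), 1.0)
        assert r.mask.sum() == 3

    def test_geotiff_and_ascii_agree(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 9)).round(6)
        r = ClimateRaster(vals, (-3.0, 10.0, 1.5, 13.0), 0.5,
                          variable_id="BIO6")
        write_raster(r, tmp_path / "g.asc")
        write_raster(r, tmp_path / "g.tif")
        a = read_raster(tmp_path / "g.asc")
        t = read_raster(tmp_path / "g.tif")
        np.testing.assert_allclose(a.values, t.values, atol=1e-12)
        assert a.extent == pytest.approx(t.extent)
        assert a.resolution == pytest.approx(t.resolution)

    def test_roundtrip_identity(self, tmp_path):
        vals = np.array([[1.0, -9999.0], [3.5, 4.25]])
        r = ClimateRaster(vals, (10.0, 20.0, 11.0, 21.0), 0.5)
        for name in ("rt.asc", "rt.tif"):
            write_raster(r, tmp_path / name)
            back = read_raster(tmp_path / name)
            np.testing.assert_array_equal(back.values, r.values)
            np.testing.assert_array_equal(back.mask, r.mask)
            assert back.extent == pytest.approx(r.extent)

    def test_projected_crs_rejected(self, tmp_path):
        import tifffile
        geo_keys = (1, 1, 0, 1, 1024, 0, 1, 1)  # model type 1 = projected
        tifffile.imwrite(tmp_path / "p.tif", np.zeros((4, 4)), extratags=[
            (33550, "d", 3, (1.0, 1.0, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, 0.0, 4.0, 0.0)),
            (34735, "H", len(geo_keys), geo_keys)])
        with pytest.raises(RasterError, match="not geographic"):
            read_raster(tmp_path / "p.tif")

    def test_shape_extent_mismatch_rejected(self):
        with pytest.raises(RasterError, match="inconsistent"):
            ClimateRaster(np.zeros((3, 3)), (0, 0, 4, 3), 1.0)


class TestSpeciesGroups:
    def test_species_grouped(self):
        occ = pd.DataFrame({"species": ["Cinara anelia", "Cinara apini",
                                        "Cinara pinea"],
                            "lon": [1.0, 2.0, 3.0], "lat": [1.0, 2.0, 3.0]})
        mapping = {"Cinara anelia": "Anelia", "Cinara apini": "Anelia"}
        out = apply_species_groups(occ, mapping)
        assert list(out["species"]) == ["Anelia", "Anelia", "Cinara pinea"]

    def test_empty_map_is_identity(self, occ_simple):
        pd.testing.assert_frame_equal(
            apply_species_groups(occ_simple, {}), occ_simple)

    def test_drop_list_removes_species(self, occ_simple):
        out = apply_species_groups(occ_simple, {}, drop_list={"a"})
        assert set(out["species"]) == {"b"}

    def test_idempotent(self, occ_simple):
        mapping = {"a": "G"}
        once = apply_species_groups(occ_simple, mapping)
        twice = apply_species_groups(once, mapping)
        pd.testing.assert_frame_equal(once, twice)


class TestMinOccurrenceFilter:
    @staticmethod
    def _occ(counts: dict) -> pd.DataFrame:
        rows = [{"species": sp, "lon": float(i), "lat": float(i % 80)}
                for sp, n in counts.items() for i in range(n)]
        return pd.DataFrame(rows)

    def test_species_below_threshold_removed(self, tree5):
        occ = self._occ({"A": 6, "B": 5, "C": 4, "D": 5, "E": 5})
        out, pruned = filter_min_occurrences(occ, tree5, min_n=5)
        assert "C" not in set(out["species"])
        assert "C" not in pruned.tip_names
        assert pruned.n_tips == 4

    def test_min_n_one_is_identity(self, tree5):
        occ = self._occ({t: 1 for t in tree5.tip_names})
        out, pruned = filter_min_occurrences(occ, tree5, min_n=1)
        assert len(out) == len(occ)
        assert pruned.n_tips == 5

    def test_depths_preserved_after_pruning(self, tree5):
        occ = self._occ({"A": 6, "B": 1, "C": 6, "D": 1, "E": 6})
        _, pruned = filter_min_occurrences(occ, tree5, min_n=5)
        depths = pruned.tip_depths()
        assert set(depths) == {"A", "C", "E"}
        assert all(d == pytest.approx(3.0) for d in depths.values())

    def test_too_few_tips_errors(self, tree5):
        occ = self._occ({"A": 6, "B": 6, "C": 1, "D": 1, "E": 1})
        with pytest.raises(TreeError, match="< 3"):
            filter_min_occurrences(occ, tree5, min_n=5)

    @pytest.mark.parametrize("seed", range(5))
    def test_pruned_vcv_equals_subselected_vcv(self, seed):
        """Pruning commutes with the phylogenetic covariance: prune-then-vcv
        equals vcv-then-delete-rows/cols, on random 10-tip trees."""
        tree = simulate_yule_tree(10, seed=seed)
        keep = sorted(tree.tip_names)[: 6]
        C_full = tree_vcv(tree).loc[keep, keep]
        C_pruned = tree_vcv(tree.prune_to(keep)).loc[keep, keep]
        np.testing.assert_allclose(C_pruned.to_numpy(), C_full.to_numpy(),
                                   atol=1e-10)
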