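"""Overlay, polygon adjacency rules and site distances."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from patchrank.spatial import (
    CRSMismatchError,
    PatchLayer,
    SiteSet,
    drop_slivers,
    min_site_distance,
    overlay_intersection,
    polygons_to_graph,
    read_patch_layer,
    write_patch_layer,
)


def _layer(polys, crs=None, land_use=None):
    return PatchLayer(
        ids=tuple(range(len(polys))),
        polygons=tuple(polys),
        land_use=tuple(land_use) if land_use else None,
        crs=crs,
    )


def _grid_layer(rows, cols, skip=()):
    polys, ids = [], []
    for r in range(rows):
        for c in range(cols):
            if (r, c) in skip:
                continue
            ids.append((r, c))
            polys.append(box(c, r, c + 1, r + 1))
    return PatchLayer(ids=tuple(ids), polygons=tuple(polys))


class TestOverlay:
    def test_exact_cover_identity(self):
        sq = box(0, 0, 1, 1)
        out = overlay_intersection(_layer([sq]), _layer([sq], land_use=["forest"]))
        assert len(out) == 1
        assert out.polygons[0].equals(sq)
        assert out.land_use == ("forest",)

    def test_straddling_cell_splits(self):
        cell = box(0, 0, 2, 1)
        halves = _layer([box(0, 0, 1, 1), box(1, 0, 2, 1)], land_use=["a", "b"])
        out = overlay_intersection(_layer([cell]), halves)
        assert len(out) == 2
        assert sorted(p.area for p in out.polygons) == [1.0, 1.0]
        assert sorted(out.land_use) == ["a", "b"]
        assert out.ids == (0, 1)  # fresh sequential ids

    def test_empty_intersection(self):
        out = overlay_intersection(
            _layer([box(0, 0, 1, 1)]), _layer([box(5, 5, 6, 6)])
        )
        assert len(out) == 0

    def test_crs_mismatch(self):
        with pytest.raises(CRSMismatchError, match="EPSG:3035"):
            overlay_intersection(
                _layer([box(0, 0, 1, 1)], crs="EPSG:3035"),
                _layer([box(0, 0, 1, 1)], crs="EPSG:32632"),
            )

    def test_total_area_matches_pairwise_oracle(self, rng):
        def rand_boxes(k):
            out = []
            for _ in range(k):
                x, y = rng.uniform(0, 8, size=2)
                w, h = rng.uniform(0.5, 3, size=2)
                out.append(box(x, y, x + w, y + h))
            return out

        cells, cover = rand_boxes(12), rand_boxes(12)
        out = overlay_intersection(_layer(cells), _layer(cover))
        total = sum(p.area for p in out.polygons)
        oracle = sum(c.intersection(l).area for c in cells for l in cover)
        assert total == pytest.approx(oracle, abs=1e-9)


class TestPolygonsToGraph:
    def test_2x2_rook(self):
        g = polygons_to_graph(_grid_layer(2, 2), "rook")
        assert g.n_edges == 4

    def test_2x2_queen_includes_diagonals(self):
        g = polygons_to_graph(_grid_layer(2, 2), "queen")
        assert g.n_edges == 6

    def test_5x5_with_hole_matches_enumeration(self):
        layer = _grid_layer(5, 5, skip={(2, 2)})
        g = polygons_to_graph(layer, "rook")
        expected = set()
        for r, c in layer.ids:
            for dr, dc in ((0, 1), (1, 0)):
                nb = (r + dr, c + dc)
                if nb in layer.ids:
                    expected.add(frozenset([(r, c), nb]))
        assert {frozenset(e) for e in g.edges} == expected

    def test_queen_superset_of_rook(self, rng):
        skip = {(int(r), int(c)) for r, c in rng.integers(0, 4, size=(4, 2))}
        layer = _grid_layer(4, 4, skip=skip)
        rook = {frozenset(e) for e in polygons_to_graph(layer, "rook").edges}
        queen = {frozenset(e) for e in polygons_to_graph(layer, "queen").edges}
        assert rook <= queen

    def test_invalid_geometry_repaired(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting
        layer = PatchLayer(ids=(0, 1), polygons=(bowtie, box(2, 0, 3, 1)))
        g = polygons_to_graph(layer, "rook")
        assert g.n_nodes == 2  # repair pass, then predicates

    def test_bad_rule_rejected(self):
        with pytest.raises(ValueError):
            polygons_to_graph(_grid_layer(1, 2), "bishop")


class TestMinSiteDistance:
    def test_patch_inside_site(self):
        sites = SiteSet(ids=("s",), polygons=(box(0, 0, 10, 10),))
        d = min_site_distance(_layer([box(2, 2, 3, 3)]), sites)
        assert d[0] == 0.0

    def test_unit_gap(self):
        sites = SiteSet(ids=("s",), polygons=(box(0, 0, 1, 1),))
        d = min_site_distance(_layer([box(2, 0, 3, 1)]), sites)
        assert d[0] == pytest.approx(1.0)

    def test_adding_site_only_lowers(self, rng):
        patches = _layer([box(x, 0, x + 1, 1) for x in range(0, 12, 3)])
        s1 = SiteSet(ids=("a",), polygons=(box(-5, 0, -4, 1),))
        s2 = SiteSet(ids=("a", "b"),
                     polygons=(box(-5, 0, -4, 1), box(20, 0, 21, 1)))
        d1, d2 = min_site_distance(patches, s1), min_site_distance(patches, s2)
        assert all(d2[k] <= d1[k] for k in d1)

    def test_matches_boundary_sampling_oracle(self, rng):
        patches = []
        for _ in range(6):
            x, y = rng.uniform(0, 10, size=2)
            patches.append(box(x, y, x + 1, y + 1))
        site = box(12, 12, 14, 14)
        d = min_site_distance(_layer(patches), SiteSet(("s",), (site,)))
        ts = np.linspace(0, 1, 400)
        for i, p in enumerate(patches):
            pts = [p.exterior.interpolate(t, normalized=True) for t in ts]
            spts = [site.exterior.interpolate(t, normalized=True) for t in ts]
            oracle = min(a.distance(b) for a in pts for b in spts)
            assert d[i] == pytest.approx(oracle, abs=1e-2)

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            min_site_distance(_layer([box(0, 0, 1, 1)]), SiteSet((), ()))


class TestLayerUtilities:
    def test_drop_slivers(self):
        layer = _layer([box(0, 0, 1, 1), box(5, 5, 5.01, 5.01)])
        out = drop_slivers(layer, min_area=0.1)
        assert len(out) == 1

    def test_geojson_round_trip(self, tmp_path):
        layer = _layer([box(0, 0, 1, 1), box(1, 0, 2, 1)], land_use=["a", "b"],
                       crs="EPSG:3035")
        path = tmp_path / "patches.geojson"
        write_patch_layer(layer, path, extra_properties={0: {"rank": 1}})
        back = read_patch_layer(path)
        assert back.ids == (0, 1)
        assert back.land_use == ("a", "b")
        assert back.crs == "EPSG:3035"
        assert back.polygons[0].equals(layer.polygons[0])
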