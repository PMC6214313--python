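"""Geospatial front end: overlay, polygon adjacency, site distances.

Turns vector layers into the inputs of the ranking pipeline: corridor
cells are intersected with the land-cover map to obtain patches that are
homogeneous in land-use code, patch adjacency becomes the graph, and the
minimum boundary-to-boundary distance from each patch to a protected site
becomes the D metric.

All geometry work happens on projected planar coordinates via shapely;
layers must already share one projected CRS (declared CRS names, when
present, are compared and a mismatch is an error — there is no
reprojection here).  Distances are Euclidean in CRS units; at corridor
scale the projection distortion is negligible relative to patch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

from shapely import make_valid
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .graph import PatchGraph, build_graph

__all__ = [
    "PatchLayer",
    "SiteSet",
    "CRSMismatchError",
    "InvalidGeometryError",
    "overlay_intersection",
    "polygons_to_graph",
    "min_site_distance",
    "drop_slivers",
    "read_patch_layer",
    "write_patch_layer",
    "read_site_set",
]


class CRSMismatchError(ValueError):
    """Two layers declare different coordinate reference systems."""


class InvalidGeometryError(ValueError):
    """Geometries remain invalid after the repair pass."""


def _repair(geom: BaseGeometry, gid: Hashable) -> BaseGeometry:
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if not fixed.is_valid:
        raise InvalidGeometryError(f"geometry {gid!r} is invalid and unrepairable")
    return fixed


@dataclass(frozen=True)
class PatchLayer:
    """Polygon patches with unique ids and optional land-use codes."""

    ids: tuple[Hashable, ...]
    polygons: tuple[BaseGeometry, ...]
    land_use: tuple[str, ...] | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("patch ids must be unique")
        if len(self.ids) != len(self.polygons):
            raise ValueError("ids and polygons differ in length")
        if self.land_use is not None and len(self.land_use) != len(self.ids):
            raise ValueError("land_use must align with ids")

    def __len__(self) -> int:
        return len(self.ids)

    def repaired(self) -> "PatchLayer":
        """Return the layer with every geometry made valid.

        Unrepairable features raise :class:`InvalidGeometryError` listing
        their ids rather than being silently dropped.
        """
        bad, fixed = [], []
        for gid, geom in zip(self.ids, self.polygons):
            try:
                fixed.append(_repair(geom, gid))
            except InvalidGeometryError:
                bad.append(gid)
        if bad:
            raise InvalidGeometryError(f"unrepairable geometries: {bad}")
        return PatchLayer(self.ids, tuple(fixed), self.land_use, self.crs)


@dataclass(frozen=True)
class SiteSet:
    """Protected-site polygons (the distance anchors)."""

    ids: tuple[Hashable, ...]
    polygons: tuple[BaseGeometry, ...]
    crs: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("site ids must be unique")
        if len(self.ids) != len(self.polygons):
            raise ValueError("ids and polygons differ in length")

    def __len__(self) -> int:
        return len(self.ids)


def _check_crs(a: str | None, b: str | None) -> str | None:
    if a is not None and b is not None and a != b:
        raise CRSMismatchError(f"layer CRS {a!r} does not match {b!r}")
    return a or b


def overlay_intersection(
    corridor_cells: PatchLayer, landcover: PatchLayer
) -> PatchLayer:
    """Intersect corridor cells with land-cover patches.

    Output polygons are the pairwise intersections with positive area,
    each carrying the land-use code of its land-cover parent and a fresh
    sequential integer id.  An empty intersection yields an empty layer.
    """
    crs = _check_crs(corridor_cells.crs, landcover.crs)
    cells = corridor_cells.repaired()
    cover = landcover.repaired()

    tree = STRtree(cover.polygons)
    out_polys, out_use = [], []
    for cell in cells.polygons:
        for j in sorted(tree.query(cell, predicate="intersects")):
            inter = cell.intersection(cover.polygons[j])
            if inter.area > 0:
                out_polys.append(inter)
                out_use.append(cover.land_use[j] if cover.land_use else "")
    return PatchLayer(
        ids=tuple(range(len(out_polys))),
        polygons=tuple(out_polys),
        land_use=tuple(out_use),
        crs=crs,
    )


def polygons_to_graph(layer: PatchLayer, adjacency: str = "rook") -> PatchGraph:
    """Derive the patch-adjacency graph from a polygon layer.

    ``rook`` (default) links patches whose boundaries share a segment of
    positive length; ``queen`` also links patches sharing only isolated
    boundary points (corners).  The queen edge set is always a superset of
    the rook one.
    """
    if adjacency not in ("rook", "queen"):
        raise ValueError(f"adjacency rule must be 'rook' or 'queen', got {adjacency!r}")
    lay = layer.repaired()
    tree = STRtree(lay.polygons)
    edges = []
    for i, geom in enumerate(lay.polygons):
        for j in sorted(tree.query(geom, predicate="intersects")):
            if j <= i:
                continue
            rel = geom.relate(lay.polygons[j])
            # DE-9IM position 4 = boundary/boundary intersection dimension
            if rel[4] == "1" or (adjacency == "queen" and rel[4] == "0"):
                edges.append((lay.ids[i], lay.ids[j]))
    attrs: dict[Hashable, dict] = {
        gid: ({"land_use": lu} if lay.land_use else {})
        for gid, lu in zip(lay.ids, lay.land_use or [""] * len(lay))
    }
    return build_graph(edges, attrs)


def min_site_distance(
    layer: PatchLayer, sites: SiteSet
) -> dict[Hashable, float]:
    """Minimum boundary-to-boundary distance from each patch to any site.

    D(v) = min over sites s of d(s, v), Euclidean in CRS units; a patch
    touching or intersecting a site has D = 0.
    """
    if len(sites) == 0:
        raise ValueError(
            "site set is empty: exclude the distance metric from the "
            "combined score instead"
        )
    _check_crs(layer.crs, sites.crs)
    lay = layer.repaired()
    return {
        gid: min(geom.distance(s) for s in sites.polygons)
        for gid, geom in zip(lay.ids, lay.polygons)
    }


def drop_slivers(layer: PatchLayer, min_area: float = 0.0) -> PatchLayer:
    """Drop patches with area below ``min_area`` (0 keeps everything).

    Post-overlay slivers are a known source of enclave noise in source
    spatial data.
    """
    keep = [i for i, g in enumerate(layer.polygons) if g.area >= min_area]
    return PatchLayer(
        ids=tuple(layer.ids[i] for i in keep),
        polygons=tuple(layer.polygons[i] for i in keep),
        land_use=tuple(layer.land_use[i] for i in keep) if layer.land_use else None,
        crs=layer.crs,
    )


# ---------------------------------------------------------------------------
# GeoJSON I/O

def read_patch_layer(
    path: str | Path,
    id_property: str = "id",
    land_use_property: str | None = "land_use",
) -> PatchLayer:
    """Read a polygon layer from GeoJSON.

    Feature ids come from the ``id_property`` property (falling back to the
    feature ``id`` member, then to the feature index); a legacy top-level
    ``crs`` name is honoured when present.
    """
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    crs = None
    if isinstance(data.get("crs"), dict):
        crs = data["crs"].get("properties", {}).get("name")
    ids, polys, uses = [], [], []
    has_use = False
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        gid = props.get(id_property, feat.get("id", i))
        ids.append(gid)
        polys.append(geom_shape(feat["geometry"]))
        lu = props.get(land_use_property) if land_use_property else None
        has_use = has_use or lu is not None
        uses.append("" if lu is None else str(lu))
    return PatchLayer(
        ids=tuple(ids),
        polygons=tuple(polys),
        land_use=tuple(uses) if has_use else None,
        crs=crs,
    )


def read_site_set(path: str | Path, id_property: str = "id") -> SiteSet:
    """Read protected-site polygons from GeoJSON."""
    layer = read_patch_layer(path, id_property=id_property, land_use_property=None)
    return SiteSet(ids=layer.ids, polygons=layer.polygons, crs=layer.crs)


def write_patch_layer(
    layer: PatchLayer,
    path: str | Path,
    extra_properties: Mapping[Hashable, Mapping[str, object]] | None = None,
) -> None:
    """Write a layer to GeoJSON, optionally joining per-patch attributes.

    ``extra_properties`` maps patch id to additional properties (for
    example ranking columns), enabling map styling downstream.
    """
    features = []
    for i, (gid, geom) in enumerate(zip(layer.ids, layer.polygons)):
        props: dict = {"id": gid}
        if layer.land_use is not None:
            props["land_use"] = layer.land_use[i]
        if extra_properties and gid in extra_properties:
            props.update(extra_properties[gid])
        features.append(
            {"type": "Feature", "properties": props, "geometry": geom_mapping(geom)}
        )
    doc = {"type": "FeatureCollection", "features": features}
    if layer.crs:
        doc["crs"] = {"type": "name", "properties": {"name": layer.crs}}
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
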