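"""Spatial primitives: queen contiguity weights and the border proximity factor.

The border proximity factor (BPF) of a district is the mean Euclidean
distance of its boundary from its own state's border, capturing how close a
district sits to an interstate border (districts near borders tend to share
norms with their cross-border neighbours).  By default only *interstate*
borders count — the outer frame of the study area is excluded, so a coastal
district far from any interstate border keeps a large BPF.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape
from shapely.ops import unary_union


class GeometryInputError(ValueError):
    pass


class BorderUndefinedError(RuntimeError):
    pass


def parse_geography(geography: dict):
    """GeoJSON feature collection -> (district ids, state ids, shapely polygons).

    Validates uniqueness of district ids and polygon validity.
    """
    ids: list[str] = []
    states: list[str] = []
    polys = []
    for feat in geography["features"]:
        props = feat.get("properties", {})
        did = props.get("district_id")
        if did is None:
            raise GeometryInputError("feature missing district_id property")
        if did in ids:
            raise GeometryInputError(f"duplicate district id {did!r}")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GeometryInputError(f"invalid polygon for district {did!r}")
        ids.append(str(did))
        states.append(str(props.get("state_id", "S1")))
        polys.append(geom)
    return ids, states, polys


@dataclass
class SpatialWeights:
    """Row-standardised spatial weights over districts.

    ``neighbours[i]`` lists the ids adjacent to district ``i`` and
    ``weights[i]`` the matching weights.  The underlying adjacency is
    symmetric; row-standardisation divides each row by its neighbour count,
    so rows of isolated districts are all-zero and their ids appear in
    ``neighbourless_ids``.
    """

    ids: list[str]
    neighbours: dict[str, list[str]]
    weights: dict[str, list[float]]
    row_standardized: bool = True
    neighbourless_ids: list[str] = field(default_factory=list)

    def n_neighbours(self, district_id: str) -> int:
        return len(self.neighbours[district_id])

    def to_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Dense weight matrix in the given id order (default: self.ids)."""
        order = list(order) if order is not None else list(self.ids)
        index = {d: k for k, d in enumerate(order)}
        W = np.zeros((len(order), len(order)))
        for i in order:
            for j, w in zip(self.neighbours[i], self.weights[i]):
                W[index[i], index[j]] = w
        return W

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "ids": self.ids,
            "neighbours": self.neighbours,
            "weights": self.weights,
            "row_standardized": self.row_standardized,
            "neighbourless_ids": self.neighbourless_ids,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text: str) -> "SpatialWeights":
        text = path_or_text
        if not text.lstrip().startswith("{"):
            with open(path_or_text) as fh:
                text = fh.read()
        d = json.loads(text)
        return cls(
            ids=d["ids"],
            neighbours=d["neighbours"],
            weights=d["weights"],
            row_standardized=d["row_standardized"],
            neighbourless_ids=d["neighbourless_ids"],
        )


def queen_weights(geography: dict) -> SpatialWeights:
    """Queen-contiguity weights: districts sharing any boundary point are
    neighbours; rows are standardised to sum to 1 (isolates excluded)."""
    ids, _, polys = parse_geography(geography)
    tree = shapely.STRtree(polys)
    neighbours: dict[str, list[str]] = {i: [] for i in ids}
    for k, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            j = int(j)
            if j != k:
                neighbours[ids[k]].append(ids[j])
    # keep neighbour lists in id order for reproducible serialisation
    weights: dict[str, list[float]] = {}
    neighbourless = []
    for i in ids:
        neighbours[i] = sorted(neighbours[i])
        k = len(neighbours[i])
        if k == 0:
            neighbourless.append(i)
            weights[i] = []
        else:
            weights[i] = [1.0 / k] * k
    return SpatialWeights(
        ids=ids,
        neighbours=neighbours,
        weights=weights,
        row_standardized=True,
        neighbourless_ids=neighbourless,
    )


def _lines_of(geom) -> list:
    """Extract the 1-dimensional pieces of any shapely geometry."""
    if geom.is_empty:
        return []
    if geom.geom_type in ("LineString", "LinearRing"):
        return [geom]
    if geom.geom_type in ("MultiLineString", "GeometryCollection"):
        out = []
        for g in geom.geoms:
            out.extend(_lines_of(g))
        return out
    return []


def state_borders(
    geography: dict, include_outer_frame: bool = False
) -> dict[str, shapely.Geometry]:
    """Per-state border geometry.

    With ``include_outer_frame=False`` (default) a state's border is the set
    of line segments it shares with *other* states; with True it is the full
    outline of the state's territory.
    """
    ids, states, polys = parse_geography(geography)
    state_polys = {
        s: unary_union([p for p, st in zip(polys, states) if st == s])
        for s in dict.fromkeys(states)
    }
    borders: dict[str, shapely.Geometry] = {}
    for s, sp in state_polys.items():
        if include_outer_frame:
            borders[s] = sp.boundary
            continue
        pieces = []
        for t, tp in state_polys.items():
            if t != s:
                pieces.extend(_lines_of(sp.intersection(tp)))
        borders[s] = unary_union(pieces) if pieces else shapely.LineString()
    return borders


def _sample_boundary(poly, n: int) -> np.ndarray:
    """n points uniformly by arc length along a polygon's boundary."""
    lines = _lines_of(poly.boundary)
    lengths = np.array([ln.length for ln in lines])
    total = lengths.sum()
    if total == 0:
        raise GeometryInputError("degenerate district boundary")
    positions = (np.arange(n) + 0.5) / n * total
    cuts = np.concatenate([[0.0], np.cumsum(lengths)])
    pts = []
    for s in positions:
        k = min(np.searchsorted(cuts, s, side="right") - 1, len(lines) - 1)
        p = lines[k].interpolate(s - cuts[k])
        pts.append([p.x, p.y])
    return np.asarray(pts)


def compute_bpf(
    geography: dict,
    n_boundary_samples: int = 256,
    bpf_method: str = "boundary",
    include_outer_frame: bool = False,
) -> pd.DataFrame:
    """Border proximity factor per district, in map units.

    ``bpf_method='boundary'`` (default): mean, over ``n_boundary_samples``
    points placed uniformly by arc length along the district boundary, of the
    Euclidean distance to the nearest point of the district's own state
    border.  ``bpf_method='centroid'``: distance from the district centroid
    instead.
    """
    if bpf_method not in ("boundary", "centroid"):
        raise GeometryInputError(f"unknown bpf_method {bpf_method!r}")
    ids, states, polys = parse_geography(geography)
    borders = state_borders(geography, include_outer_frame=include_outer_frame)
    for s, b in borders.items():
        if b.is_empty:
            raise BorderUndefinedError(
                f"state {s!r} has no interstate border; for single-state maps "
                "pass include_outer_frame=True"
            )
    out = []
    for did, s, poly in zip(ids, states, polys):
        border = borders[s]
        if bpf_method == "centroid":
            bpf = poly.centroid.distance(border)
        else:
            pts = _sample_boundary(poly, n_boundary_samples)
            bpf = float(
                np.mean(shapely.distance(shapely.points(pts), border))
            )
        out.append({"district_id": did, "state_id": s, "bpf": bpf})
    return pd.DataFrame(out)
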