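"""Topology-map data model and graph-level transformations.

A :class:`ConduitNetwork` is the "topology map" of a tubular mesh: vertices
are junctions or tips, edges are centerline polylines carrying a radius at
every sample point.  Self-loops and parallel edges are permitted because the
real conduit mesh contains cycles.  Graph-level cleanup used by the analysis
lives here as free functions: :func:`heal` (dead-end pruning/joining),
:func:`crop_sphere` (spherical subregion extraction), :func:`apply_shrinkage`
(embedding-shrinkage length correction) and :func:`components`.

All coordinates are in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Edge",
    "ConduitNetwork",
    "SubregionSpec",
    "edge_direction",
    "heal",
    "crop_sphere",
    "apply_shrinkage",
    "merge_degree_two",
    "components",
]


def _polyline_length(xyz: np.ndarray) -> float:
    if len(xyz) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))


@dataclass
class Edge:
    """A tube segment: centerline polyline with per-point radii.

    ``points`` is an ``(n, 4)`` float array of ``x, y, z, r``; the first and
    last point coincide with the positions of the endpoint vertices ``v0``
    and ``v1``.
    """

    id: int
    v0: int
    v1: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise ValueError("edge points must be an (n, 4) array of x,y,z,r")
        if len(self.points) < 2:
            raise ValueError("edge polyline needs at least 2 points")

    @property
    def xyz(self) -> np.ndarray:
        return self.points[:, :3]

    @property
    def radii(self) -> np.ndarray:
        return self.points[:, 3]

    @property
    def length(self) -> float:
        return _polyline_length(self.xyz)

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))

    @property
    def mean_diameter(self) -> float:
        return 2.0 * self.mean_radius

    def arc_coords(self) -> np.ndarray:
        """Cumulative arc length at each polyline point (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.xyz, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def point_at_arc(self, s: float) -> np.ndarray:
        """Interpolated centerline position at arc coordinate ``s``."""
        cum = self.arc_coords()
        s = float(np.clip(s, 0.0, cum[-1]))
        return np.array([np.interp(s, cum, self.xyz[:, i]) for i in range(3)])

    def copy(self) -> "Edge":
        return Edge(self.id, self.v0, self.v1, self.points.copy())


@dataclass
class SubregionSpec:
    """A spherical region of interest (default diameter 100 um)."""

    center: tuple[float, float, float]
    diameter: float = 100.0
    zone_label: str = "none"  # deep | superficial | none

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("subregion diameter must be > 0")
        if self.zone_label not in ("deep", "superficial", "none"):
            raise ValueError(f"unknown zone label {self.zone_label!r}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume_mm3(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius**3 * 1e-9


class ConduitNetwork:
    """Vertices + polyline edges describing a connected tube network."""

    def __init__(self, meta: dict | None = None):
        self.vertices: dict[int, np.ndarray] = {}
        self.edges: dict[int, Edge] = {}
        self.meta: dict = dict(meta) if meta else {}
        #: vertex ids created by cutting edges at a crop boundary; these are
        #: not biological tips and are excluded from degree statistics.
        self.boundary: set[int] = set()
        self._next_vid = 0
        self._next_eid = 0

    # -- construction -----------------------------------------------------
    def add_vertex(self, pos, vid: int | None = None) -> int:
        if vid is None:
            vid = self._next_vid
        if vid in self.vertices:
            raise ValueError(f"vertex id {vid} already present")
        self.vertices[vid] = np.asarray(pos, dtype=float).reshape(3)
        self._next_vid = max(self._next_vid, vid + 1)
        return vid

    def add_edge(self, v0: int, v1: int, points, eid: int | None = None) -> int:
        if v0 not in self.vertices or v1 not in self.vertices:
            raise ValueError("edge endpoints must be existing vertices")
        if eid is None:
            eid = self._next_eid
        if eid in self.edges:
            raise ValueError(f"edge id {eid} already present")
        self.edges[eid] = Edge(eid, v0, v1, np.asarray(points, dtype=float))
        self._next_eid = max(self._next_eid, eid + 1)
        return eid

    def remove_edge(self, eid: int) -> None:
        del self.edges[eid]

    def remove_vertex(self, vid: int) -> None:
        if any(e.v0 == vid or e.v1 == vid for e in self.edges.values()):
            raise ValueError("cannot remove a vertex with incident edges")
        del self.vertices[vid]
        self.boundary.discard(vid)

    # -- queries ----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def incident(self, vid: int) -> list[tuple[int, int]]:
        """Incident edge-ends at a vertex as ``(edge_id, end)`` pairs.

        ``end`` is 0 if the vertex is the edge's ``v0`` and 1 if it is
        ``v1``; a self-loop contributes both ends.
        """
        out = []
        for e in self.edges.values():
            if e.v0 == vid:
                out.append((e.id, 0))
            if e.v1 == vid:
                out.append((e.id, 1))
        return out

    def degrees(self) -> dict[int, int]:
        """Vertex degree = number of incident edge-ends (self-loops count twice)."""
        deg = {vid: 0 for vid in self.vertices}
        for e in self.edges.values():
            deg[e.v0] += 1
            deg[e.v1] += 1
        return deg

    def total_length(self) -> float:
        return float(sum(e.length for e in self.edges.values()))

    def copy(self) -> "ConduitNetwork":
        out = ConduitNetwork(meta=dict(self.meta))
        out.vertices = {vid: p.copy() for vid, p in self.vertices.items()}
        out.edges = {eid: e.copy() for eid, e in self.edges.items()}
        out.boundary = set(self.boundary)
        out._next_vid = self._next_vid
        out._next_eid = self._next_eid
        return out

    def to_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.vertices)
        for e in self.edges.values():
            g.add_edge(e.v0, e.v1, key=e.id)
        return g

    # -- serialization ----------------------------------------------------
    def to_json_obj(self) -> dict:
        meta = dict(self.meta)
        meta["boundary_vertices"] = sorted(self.boundary)
        return {
            "vertices": [
                {"id": vid, "x": p[0], "y": p[1], "z": p[2]}
                for vid, p in sorted(self.vertices.items())
            ],
            "edges": [
                {
                    "id": e.id,
                    "v0": e.v0,
                    "v1": e.v1,
                    "points": [[float(v) for v in row] for row in e.points],
                }
                for e in sorted(self.edges.values(), key=lambda e: e.id)
            ],
            "meta": meta,
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ConduitNetwork":
        meta = dict(obj.get("meta", {}))
        boundary = set(meta.pop("boundary_vertices", []))
        net = cls(meta=meta)
        for v in obj["vertices"]:
            net.add_vertex((v["x"], v["y"], v["z"]), vid=int(v["id"]))
        for e in obj["edges"]:
            net.add_edge(int(e["v0"]), int(e["v1"]), e["points"], eid=int(e["id"]))
        net.boundary = boundary
        return net

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1))

    @classmethod
    def load_json(cls, path) -> "ConduitNetwork":
        return cls.from_json_obj(json.loads(Path(path).read_text()))

    def save_csv_tables(self, directory) -> None:
        """Write vertices.csv and edges.csv companions to the JSON format."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        deg = self.degrees()
        pd.DataFrame(
            [
                {
                    "id": vid,
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                    "degree": deg[vid],
                    "boundary": vid in self.boundary,
                }
                for vid, p in sorted(self.vertices.items())
            ]
        ).to_csv(directory / "vertices.csv", index=False)
        pd.DataFrame(
            [
                {
                    "id": e.id,
                    "v0": e.v0,
                    "v1": e.v1,
                    "length": e.length,
                    "mean_diameter": e.mean_diameter,
                    "n_points": len(e.points),
                }
                for e in sorted(self.edges.values(), key=lambda e: e.id)
            ]
        ).to_csv(directory / "edges.csv", index=False)


def edge_direction(net: ConduitNetwork, eid: int, end: int,
                   chord: float = 5.0) -> np.ndarray | None:
    """Arc-local unit direction of an edge leaving one of its endpoints.

    The direction is the chord from the endpoint vertex (``end`` 0 or 1)
    to the centerline point ``chord`` um along the edge, or the far
    endpoint if the edge is shorter.  Arc-local chords resist the voxel
    jitter of raw traced polylines.  Returns ``None`` for a degenerate
    (zero-extent) chord.
    """
    e = net.edges[eid]
    pts = e.xyz if end == 0 else e.xyz[::-1]
    cum = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    s = min(chord, cum[-1])
    target = np.array([np.interp(s, cum, pts[:, i]) for i in range(3)])
    v = target - pts[0]
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else None


# -- graph-level operations ------------------------------------------------


def heal(net: ConduitNetwork, max_len: float = 15.0) -> ConduitNetwork:
    """Resolve short dead-end branches by joining or pruning.

    Every degree-1 vertex whose incident edge is no longer than ``max_len``
    um is *joined* to the nearest other vertex within ``max_len`` um
    (Euclidean) by a new straight edge, or, when no such vertex exists,
    its dead-end edge is *pruned*.  Joining is preferred because it keeps
    the network connected for walkers.  The pass repeats until no eligible
    dead end remains; dead-end edges longer than ``max_len`` are untouched.
    """
    net = net.copy()
    events = net.meta.setdefault("heal_log", [])
    while True:
        deg = net.degrees()
        incident: dict[int, list[int]] = {vid: [] for vid in net.vertices}
        for e in net.edges.values():
            incident[e.v0].append(e.id)
            if e.v1 != e.v0:
                incident[e.v1].append(e.id)
        eligible = []
        for vid, d in deg.items():
            if d != 1:
                continue
            eid = incident[vid][0]
            if net.edges[eid].length <= max_len:
                eligible.append((vid, eid))
        if not eligible:
            break
        vids = sorted(net.vertices)
        positions = np.array([net.vertices[v] for v in vids])
        tree = cKDTree(positions)
        removed_edges: set[int] = set()
        for vid, eid in eligible:
            if eid in removed_edges:
                continue
            edge = net.edges[eid]
            other = edge.v1 if edge.v0 == vid else edge.v0
            pos = net.vertices[vid]
            # nearest vertex within max_len, excluding the spur's own ends
            idxs = tree.query_ball_point(pos, r=max_len)
            best, best_d = None, np.inf
            for i in idxs:
                tgt = vids[i]
                if tgt in (vid, other) or tgt not in net.vertices:
                    continue
                d = float(np.linalg.norm(net.vertices[tgt] - pos))
                if d < best_d:
                    best, best_d = tgt, d
            if best is not None:
                r = edge.mean_radius
                pts = np.array(
                    [[*pos, r], [*net.vertices[best], r]], dtype=float
                )
                new_eid = net.add_edge(vid, best, pts)
                incident[vid].append(new_eid)
                incident[best].append(new_eid)
                events.append({"action": "join", "vertex": vid, "to": best,
                               "edge": new_eid, "distance": best_d})
            else:
                net.remove_edge(eid)
                removed_edges.add(eid)
                events.append({"action": "prune", "vertex": vid, "edge": eid})
                for w in (vid, other):
                    if (w in net.vertices
                            and not any(ei in net.edges for ei in incident[w])):
                        net.remove_vertex(w)
    net.meta["healed_max_len"] = max_len
    return net


def crop_sphere(net: ConduitNetwork, region: SubregionSpec) -> ConduitNetwork:
    """Cut the network to a spherical subregion.

    Polyline points inside the sphere are kept; an edge crossing the
    boundary is cut at its last interior point, which becomes a new vertex
    marked as a boundary vertex (a cut is not a biological tip).  The result
    may be empty.
    """
    center = np.asarray(region.center, dtype=float)
    out = ConduitNetwork(meta=dict(net.meta))
    out.meta["subregion"] = {
        "center": list(map(float, center)),
        "diameter": region.diameter,
        "zone_label": region.zone_label,
    }

    def inside(p: np.ndarray) -> bool:
        return float(np.linalg.norm(p - center)) <= region.radius

    kept_vertices: dict[int, int] = {}  # original vid -> new vid

    def keep_vertex(vid: int) -> int:
        if vid not in kept_vertices:
            nv = out.add_vertex(net.vertices[vid])
            kept_vertices[vid] = nv
            if vid in net.boundary:
                out.boundary.add(nv)
        return kept_vertices[vid]

    for e in sorted(net.edges.values(), key=lambda e: e.id):
        mask = np.linalg.norm(e.xyz - center, axis=1) <= region.radius
        if not mask.any():
            continue
        # maximal runs of consecutive interior points
        idx = np.flatnonzero(mask)
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        for run in runs:
            if len(run) < 2:
                continue
            pts = e.points[run]
            first, last = int(run[0]), int(run[-1])
            if first == 0:
                nv0 = keep_vertex(e.v0)
            else:
                nv0 = out.add_vertex(pts[0, :3])
                out.boundary.add(nv0)
            if last == len(e.points) - 1:
                nv1 = keep_vertex(e.v1)
            else:
                nv1 = out.add_vertex(pts[-1, :3])
                out.boundary.add(nv1)
            out.add_edge(nv0, nv1, pts)
    return out


def apply_shrinkage(net: ConduitNetwork, factor: float = 1.25) -> ConduitNetwork:
    """Scale all coordinates (hence lengths) by the shrinkage correction.

    Resin embedding shrinks the tissue by an estimated 20 % per direction,
    so measured lengths are multiplied by 1/(1-0.2) = 1.25 to recover
    in-vivo scale.  Radii are left unscaled.  Applying the correction twice
    is an error.
    """
    if net.meta.get("shrinkage_corrected"):
        raise ValueError("shrinkage correction already applied")
    out = net.copy()
    for vid in out.vertices:
        out.vertices[vid] = out.vertices[vid] * factor
    for e in out.edges.values():
        e.points[:, :3] *= factor
    out.meta["shrinkage_corrected"] = True
    out.meta["shrinkage_factor"] = factor
    return out


def merge_degree_two(net: ConduitNetwork) -> ConduitNetwork:
    """Contract pass-through (degree-2) vertices, fusing their two edges.

    A degree-2 vertex is not a junction: in the junction-to-junction
    description of a tube network the two incident edges are one segment.
    Polylines and radii are concatenated; self-loops at the vertex,
    boundary-marked vertices, and pure degree-2 cycles (which keep one
    anchor vertex) are left untouched.
    """
    out = ConduitNetwork(meta=dict(net.meta))
    deg = net.degrees()
    incident: dict[int, list[tuple[int, int]]] = {v: [] for v in net.vertices}
    for e in net.edges.values():
        incident[e.v0].append((e.id, 0))
        incident[e.v1].append((e.id, 1))

    def passthrough(vid: int) -> bool:
        if deg[vid] != 2 or vid in net.boundary:
            return False
        (e1, _), (e2, _) = incident[vid]
        return e1 != e2  # a self-loop end pair is not a pass-through

    keep = [v for v in sorted(net.vertices) if not passthrough(v)]
    for vid in keep:
        out.add_vertex(net.vertices[vid], vid=vid)
        if vid in net.boundary:
            out.boundary.add(vid)

    visited: set[int] = set()

    def walk(eid: int, end_at_start: int):
        """Follow edges through pass-through vertices starting from the
        given edge end; return (far vertex, concatenated points)."""
        e = net.edges[eid]
        pts = e.points if end_at_start == 0 else e.points[::-1]
        cur = e.v1 if end_at_start == 0 else e.v0
        visited.add(eid)
        while passthrough(cur):
            (f1, _), (f2, _) = incident[cur]
            nxt = f2 if f1 == eid else f1
            if nxt in visited:
                break
            f = net.edges[nxt]
            fpts = f.points if f.v0 == cur else f.points[::-1]
            pts = np.vstack([pts, fpts[1:]])
            cur = f.v1 if f.v0 == cur else f.v0
            eid = nxt
            visited.add(eid)
        return cur, pts

    for vid in keep:
        for eid, end in incident[vid]:
            if eid in visited:
                continue
            far, pts = walk(eid, end)
            out.add_edge(vid, far, pts)
    # pure cycles: every vertex on them is a pass-through; anchor one vertex
    for e in sorted(net.edges.values(), key=lambda e: e.id):
        if e.id in visited:
            continue
        anchor = e.v0
        if anchor not in out.vertices:
            out.add_vertex(net.vertices[anchor], vid=anchor)
        far, pts = walk(e.id, 0)
        if far != anchor:  # open chain ended early; connect what we have
            if far not in out.vertices:
                out.add_vertex(net.vertices[far], vid=far)
            out.add_edge(anchor, far, pts)
        else:
            out.add_edge(anchor, anchor, pts)
    return out


def components(net: ConduitNetwork) -> list[ConduitNetwork]:
    """Partition into connected components, largest (by edge count) first."""
    g = net.to_multigraph()
    comps = []
    for nodes in nx.connected_components(g):
        sub = ConduitNetwork(meta=dict(net.meta))
        for vid in sorted(nodes):
            sub.add_vertex(net.vertices[vid], vid=vid)
            if vid in net.boundary:
                sub.boundary.add(vid)
        for e in sorted(net.edges.values(), key=lambda e: e.id):
            if e.v0 in nodes:
                sub.add_edge(e.v0, e.v1, e.points.copy(), eid=e.id)
        comps.append(sub)
    comps.sort(key=lambda c: (c.n_edges, c.n_vertices), reverse=True)
    return comps
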