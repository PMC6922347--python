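"""Quantitative 3D network statistics.

Implements the analysis read-outs of the topology map: segment and vertex
counts, diameter/length distributions, conduit volume and density,
branching angles (with a minimum-length filter against voxel jitter),
the 13-direction orientation distribution, distance-to-nearest-conduit
fields, moving-average density fields, and the deep-vs-superficial zone
comparison by two-tailed Student t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .network import ConduitNetwork, SubregionSpec, crop_sphere, edge_direction
from .volume import VolumeImage

__all__ = [
    "NetworkStats",
    "DistanceField",
    "DensityField",
    "OrientationDistribution",
    "segment_stats",
    "branching_angles",
    "orientation_distribution",
    "distance_field",
    "density_field",
    "compare_zones",
    "propose_subregion_centers",
    "subregion_table",
]

# The 13 reference axes: lines from a grid point to its 26 nearest
# neighbors, collapsed over sign -- 3 coordinate axes, 6 face diagonals,
# 4 body diagonals.
_AXES_RAW = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
], dtype=float)
REFERENCE_AXES = _AXES_RAW / np.linalg.norm(_AXES_RAW, axis=1, keepdims=True)


@dataclass
class NetworkStats:
    """Direct read-outs of a topology map."""

    n_vertices: int
    n_segments: int
    total_length: float               # um
    conduit_volume: float             # um^3, sum of pi (d/2)^2 L per edge
    diameter_values: np.ndarray       # um, per edge
    length_values: np.ndarray         # um, per edge
    degree_histogram: dict[int, int]  # boundary vertices excluded
    region_volume: float | None = None   # mm^3
    segment_density: float | None = None  # segments / mm^3

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.diameter_values)) if len(self.diameter_values) else 0.0

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.length_values)) if len(self.length_values) else 0.0


@dataclass
class DistanceField:
    """Per-voxel Euclidean distance (um) to the nearest conduit voxel."""

    grid: np.ndarray
    voxel_size: float
    fractions: dict[float, float]   # fraction of evaluated voxels below each threshold
    mean_min_distance: float


@dataclass
class DensityField:
    """Moving-average foreground density, rescaled from [0, 1] to [0, 255]."""

    grid: np.ndarray  # uint8
    cube_radius: float
    step: float


@dataclass
class OrientationDistribution:
    """Normalized projection weights over the 13 reference axes."""

    weights: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: REFERENCE_AXES.copy())


def segment_stats(net: ConduitNetwork,
                  region_volume: float | None = None) -> NetworkStats:
    """Counts, lengths, diameters and degrees of a topology map.

    ``region_volume`` (mm^3), when given, also yields the segment density.
    Vertices created by cropping at a subregion boundary are excluded from
    the degree histogram (a cut is not a biological tip).
    """
    lengths = np.array([e.length for e in net.edges.values()], dtype=float)
    diameters = np.array([e.mean_diameter for e in net.edges.values()], dtype=float)
    volume = float(np.sum(np.pi * (diameters / 2.0) ** 2 * lengths)) if len(lengths) else 0.0
    hist: dict[int, int] = {}
    for vid, d in net.degrees().items():
        if vid in net.boundary:
            continue
        hist[d] = hist.get(d, 0) + 1
    density = None
    if region_volume is not None:
        if region_volume <= 0:
            raise ValueError("region_volume must be > 0")
        density = net.n_edges / region_volume
    return NetworkStats(
        n_vertices=net.n_vertices,
        n_segments=net.n_edges,
        total_length=float(lengths.sum()) if len(lengths) else 0.0,
        conduit_volume=volume,
        diameter_values=diameters,
        length_values=lengths,
        degree_histogram=hist,
        region_volume=region_volume,
        segment_density=density,
    )


def branching_angles(net: ConduitNetwork, min_len: float = 4.0,
                     chord: float = 5.0) -> np.ndarray:
    """Pairwise angles (degrees) between branches at every junction.

    At each vertex of degree >= 3, outgoing direction vectors are computed
    for all incident edges longer than ``min_len`` um (shorter segments are
    skipped to avoid the jittering artifact of very short traced segments),
    and all pairwise angles between them are returned.
    """
    deg = net.degrees()
    angles: list[float] = []
    for vid, d in deg.items():
        if d < 3:
            continue
        dirs = []
        for eid, end in net.incident(vid):
            if net.edges[eid].length <= min_len:
                continue
            v = edge_direction(net, eid, end, chord)
            if v is not None:
                dirs.append(v)
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                c = float(np.clip(np.dot(dirs[i], dirs[j]), -1.0, 1.0))
                angles.append(np.degrees(np.arccos(c)))
    return np.array(angles, dtype=float)


def orientation_distribution(net: ConduitNetwork) -> OrientationDistribution:
    """Distribution of segment directions over the 13 reference axes.

    Each edge's end-to-end vector contributes the magnitude of its
    projection onto every axis; the 13 sums are normalized to 1.  The
    measure is invariant to subdividing an edge into collinear pieces.
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    weights = np.zeros(len(REFERENCE_AXES))
    for e in net.edges.values():
        v = e.xyz[-1] - e.xyz[0]
        weights += np.abs(REFERENCE_AXES @ v)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all segments have zero end-to-end extent")
    return OrientationDistribution(weights / total)


def distance_field(conduit_mask: VolumeImage,
                   eval_mask: VolumeImage | None = None,
                   thresholds: tuple[float, ...] = (4.0, 6.0, 8.0)) -> DistanceField:
    """Euclidean distance from every voxel to the nearest conduit voxel.

    Summary fractions (share of voxels closer than each threshold) and the
    mean minimum distance are computed over ``eval_mask`` (default: the
    whole grid).  Voxels lying on a conduit have distance 0.
    """
    fg = conduit_mask.as_bool()
    if not fg.any():
        raise ValueError("empty conduit mask")
    grid = ndimage.distance_transform_edt(~fg, sampling=conduit_mask.voxel_size)
    if eval_mask is not None:
        if eval_mask.data.shape != grid.shape:
            raise ValueError("evaluation mask grid does not match")
        sel = grid[eval_mask.as_bool()]
    else:
        sel = grid.ravel()
    fractions = {float(t): float(np.mean(sel < t)) for t in thresholds}
    return DistanceField(grid, conduit_mask.voxel_size, fractions, float(sel.mean()))


def density_field(mask: VolumeImage, cube_radius: float = 10.0,
                  step: float = 2.0) -> DensityField:
    """Moving-average foreground density on a coarser grid.

    Averages the binary mask over cubes of half-width ``cube_radius`` um
    sliding in ``step`` um increments, then rescales the [0, 1] fractions
    to [0, 255] (rounded to nearest, ties to even).
    """
    if mask.role != "mask":
        raise ValueError("density_field requires a mask volume")
    half = int(round(cube_radius / mask.voxel_size))
    if 2 * cube_radius < mask.voxel_size or half < 1:
        raise ValueError("cube smaller than a voxel")
    step_vox = max(1, int(round(step / mask.voxel_size)))
    frac = ndimage.uniform_filter(mask.data.astype(float), size=2 * half + 1,
                                  mode="reflect")
    frac = frac[::step_vox, ::step_vox, ::step_vox]
    grid = np.rint(np.clip(frac, 0.0, 1.0) * 255).astype(np.uint8)
    return DensityField(grid, cube_radius, step_vox * mask.voxel_size)


_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def _stars(p: float) -> str:
    if np.isnan(p):
        return "undefined"
    for cut, s in _STARS:
        if p < cut:
            return s
    return "ns"


def compare_zones(deep: pd.DataFrame, superficial: pd.DataFrame) -> pd.DataFrame:
    """Deep-vs-superficial comparison of per-subregion metrics.

    Both inputs hold one row per subregion and one column per metric.  For
    every shared metric the unpaired two-tailed Student t test (equal
    variances) is applied; significance stars follow the usual coding
    (* p<0.05 ... **** p<0.0001).  With zero variance in both groups the
    p value is undefined and reported as NaN.
    """
    deep = pd.DataFrame(deep)
    superficial = pd.DataFrame(superficial)
    if len(deep) < 2 or len(superficial) < 2:
        raise ValueError("need at least 2 subregions per zone")
    rows = []
    for col in [c for c in deep.columns if c in superficial.columns]:
        a = deep[col].to_numpy(dtype=float)
        b = superficial[col].to_numpy(dtype=float)
        if a.var() == 0.0 and b.var() == 0.0:
            if np.isclose(a.mean(), b.mean()):
                t, p = np.nan, np.nan  # undefined: no variance, no difference
            else:
                t, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "metric": col,
            "mean_deep": a.mean(), "sd_deep": a.std(ddof=1),
            "mean_superficial": b.mean(), "sd_superficial": b.std(ddof=1),
            "t_statistic": t, "p_value": p, "significance": _stars(p),
        })
    return pd.DataFrame(rows).set_index("metric")


def propose_subregion_centers(n: int, zone_label: str, deep_radius: float,
                              domain_radius: float, diameter: float = 100.0,
                              seed: int = 0, max_tries: int = 20000
                              ) -> list[SubregionSpec]:
    """Propose ``n`` non-overlapping spherical subregions inside one zone.

    The deep zone is the central sphere of ``deep_radius``; superficial is
    the shell out to ``domain_radius``.  Subregions are kept entirely
    inside their zone and mutually disjoint.  Mirrors the manual selection
    of subregion center points, but reproducibly.
    """
    if zone_label not in ("deep", "superficial"):
        raise ValueError("zone_label must be 'deep' or 'superficial'")
    r = diameter / 2.0
    rng = np.random.default_rng(seed)

    def in_zone(p: np.ndarray) -> bool:
        d = np.linalg.norm(p)
        if zone_label == "deep":
            return d <= deep_radius - r
        return deep_radius + r <= d <= domain_radius - r

    # greedy maximin placement: tight zones (five 100 um spheres inside a
    # 130 um-radius ball are close to a packing) defeat plain rejection
    # sampling, so each new center is the candidate farthest from the ones
    # already chosen
    pool = []
    for _ in range(max_tries):
        if len(pool) >= max(2000, 200 * n):
            break
        p = rng.uniform(-domain_radius, domain_radius, 3)
        if in_zone(p):
            pool.append(p)
    if len(pool) < n:
        raise RuntimeError(
            f"the {zone_label} zone cannot hold {diameter} um subregions "
            "(zone too thin)")
    pool = np.array(pool)
    best: list[np.ndarray] | None = None
    for _restart in range(60):
        order = rng.permutation(len(pool))
        centers = [pool[order[0]]]
        for _ in range(n - 1):
            dmin = np.min(
                np.linalg.norm(pool[:, None, :] - np.array(centers)[None, :, :],
                               axis=2), axis=1)
            k = int(np.argmax(dmin))
            if dmin[k] < diameter:
                break
            centers.append(pool[k])
        if len(centers) == n:
            best = centers
            break
    if best is None:
        raise RuntimeError(f"could not place {n} disjoint subregions in "
                           f"the {zone_label} zone")
    return [SubregionSpec(tuple(c), diameter, zone_label) for c in best]


def subregion_table(net: ConduitNetwork,
                    regions: list[SubregionSpec]) -> pd.DataFrame:
    """Per-subregion metric table (one row per cropped sphere).

    Crops the network to each subregion and tabulates the metrics used in
    the zone comparison: vertex and segment counts, conduit volume, mean
    diameter and length, combined length, and segment density.
    """
    rows = []
    for reg in regions:
        sub = crop_sphere(net, reg)
        st = segment_stats(sub, region_volume=reg.volume_mm3)
        rows.append({
            "zone": reg.zone_label,
            "n_vertices": st.n_vertices,
            "n_segments": st.n_segments,
            "conduit_volume": st.conduit_volume,
            "mean_diameter": st.mean_diameter,
            "mean_length": st.mean_length,
            "total_length": st.total_length,
            "segment_density": st.segment_density,
        })
    return pd.DataFrame(rows)
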