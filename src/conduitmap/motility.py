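"""T-cell motility simulation on an extracted conduit network.

Cells are constrained to migrate along the network centerlines, each at a
constant speed drawn once from a truncated Gaussian.  At every junction the
branch is sampled with probability proportional to ``cos(theta)^4`` of the
turning angle (branches turning by 90 degrees or more get a small floor
weight of 0.001); dead ends reverse the direction of travel.  The
coefficient of motility

    Cm = MSD(T) / (6 T)

-- mean squared displacement of the cell population from its start points
at the final time, divided by six times the duration -- summarizes the
resulting 3D dispersal like a diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ConduitNetwork, edge_direction

__all__ = [
    "MotilityConfig",
    "TrackSet",
    "MotilityResult",
    "branch_probabilities",
    "simulate",
    "estimate_cm",
    "spider_tracks",
]


@dataclass
class MotilityConfig:
    """Walk parameters.  Speeds in um/min, times in min, lengths in um."""

    mean_speed: float = 13.0
    speed_cv: float = 0.1
    n_cells: int = 5000
    duration: float = 60.0
    sample_interval: float = 5.0
    start_radius: float = 100.0
    start_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    weight_exponent: float = 4.0
    weight_floor: float = 0.001
    heal_max_len: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        n = self.duration / self.sample_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_interval must divide duration")

    @property
    def sample_times(self) -> np.ndarray:
        n = int(round(self.duration / self.sample_interval))
        return np.linspace(0.0, self.duration, n + 1)


@dataclass
class TrackSet:
    """Sampled cell paths: positions[cell, sample, xyz] at ``times``."""

    times: np.ndarray
    positions: np.ndarray
    speeds: np.ndarray
    start_refs: list[tuple[int, int]]  # (edge id, polyline point index)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_cells):
            for j, t in enumerate(self.times):
                x, y, z = self.positions[i, j]
                rows.append({"cell_id": i, "t_min": t, "x": x, "y": y, "z": z})
        return pd.DataFrame(rows)


@dataclass
class MotilityResult:
    """MSD curve and the coefficient of motility."""

    times: np.ndarray
    msd: np.ndarray        # um^2, mean squared displacement from start
    cm: float              # um^2 / min
    n_cells: int
    duration: float


def branch_probabilities(incoming_dir: np.ndarray,
                         outgoing_dirs: list[np.ndarray] | np.ndarray,
                         exponent: float = 4.0,
                         floor: float = 0.001) -> np.ndarray:
    """Branch-choice probabilities from turning angles.

    For each candidate branch with junction-leaving unit vector ``v(k)``
    and incoming junction-directed unit vector ``v(0)``, the turning angle
    is ``theta(k) = arccos(v(0) . v(k))`` and the weight is
    ``cos(theta)^exponent`` when ``cos(theta) > 0`` (forward turns), else
    the small ``floor``.  Probabilities are the normalized weights.
    """
    outgoing = np.atleast_2d(np.asarray(outgoing_dirs, dtype=float))
    if len(outgoing) == 0:
        raise ValueError("no outgoing branches (dead end)")
    cos = outgoing @ np.asarray(incoming_dir, dtype=float)
    # forward means theta < 90 deg; the epsilon keeps a numerically exact
    # right angle on the floor-weight side
    w = np.where(cos > 1e-12, np.maximum(cos, 0.0) ** exponent, floor)
    return w / w.sum()


class _Engine:
    """Pre-computed walk tables for one network."""

    def __init__(self, net: ConduitNetwork, cfg: MotilityConfig):
        self.net = net
        self.cfg = cfg
        self.pts: dict[int, np.ndarray] = {}
        self.cum: dict[int, np.ndarray] = {}
        self.length: dict[int, float] = {}
        for eid, e in net.edges.items():
            xyz = e.xyz
            cum = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(xyz, axis=0), axis=1))])
            self.pts[eid] = xyz
            self.cum[eid] = cum
            self.length[eid] = float(cum[-1])
        self.incident: dict[int, list[tuple[int, int]]] = {v: [] for v in net.vertices}
        for eid, e in net.edges.items():
            self.incident[e.v0].append((eid, 0))
            self.incident[e.v1].append((eid, 1))
        self._transitions: dict[tuple[int, int], tuple[list, np.ndarray]] = {}

    def position(self, eid: int, s: float) -> np.ndarray:
        cum, xyz = self.cum[eid], self.pts[eid]
        return np.array([np.interp(s, cum, xyz[:, i]) for i in range(3)])

    def transition(self, eid: int, end: int):
        """Candidates and cumulative probabilities on arriving at an edge end.

        Returns ``(candidates, cumprobs)``; an empty candidate list means
        a dead end (the caller reverses).  Degree-2 vertices are
        pass-throughs: their single continuation has probability 1.
        """
        key = (eid, end)
        if key in self._transitions:
            return self._transitions[key]
        e = self.net.edges[eid]
        vid = e.v1 if end == 1 else e.v0
        cands = [(k, kend) for (k, kend) in self.incident[vid] if (k, kend) != key]
        if not cands:
            out = ([], np.array([]))
        elif len(cands) == 1:
            out = (cands, np.array([1.0]))
        else:
            v_in = edge_direction(self.net, eid, end, chord=5.0)
            # v(0) is junction-directed: flip the junction-leaving chord
            v0 = -v_in if v_in is not None else None
            dirs = []
            for k, kend in cands:
                v = edge_direction(self.net, k, kend, chord=5.0)
                dirs.append(v if v is not None else np.zeros(3))
            if v0 is None:
                probs = np.full(len(cands), 1.0 / len(cands))
            else:
                probs = branch_probabilities(
                    v0, dirs, self.cfg.weight_exponent, self.cfg.weight_floor)
            out = (cands, np.cumsum(probs))
        self._transitions[key] = out
        return out


def _start_points(net: ConduitNetwork, cfg: MotilityConfig) -> list[tuple[int, int]]:
    center = np.asarray(cfg.start_center, dtype=float)
    refs = []
    for eid, e in net.edges.items():
        inside = np.linalg.norm(e.xyz - center, axis=1) <= cfg.start_radius
        refs.extend((eid, int(i)) for i in np.flatnonzero(inside))
    return refs


def simulate(net: ConduitNetwork, cfg: MotilityConfig) -> TrackSet:
    """Simulate ``cfg.n_cells`` constant-speed walks on the network.

    Each cell draws its speed once from a Gaussian (mean ``mean_speed``,
    SD ``speed_cv * mean_speed``, redrawn if <= 0), starts at a polyline
    point chosen uniformly inside the start sphere with a random initial
    direction, and is advanced along the centerlines; positions are
    recorded at the sample times.  Deterministic given ``cfg.seed``
    (per-cell substreams, independent of scheduling order).  The network
    should already be healed so that short dead ends do not skew the walk.
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    refs = _start_points(net, cfg)
    if not refs:
        raise ValueError("start sphere contains no network points")
    refs.sort()
    eng = _Engine(net, cfg)
    times = cfg.sample_times
    n_cells = cfg.n_cells
    positions = np.zeros((n_cells, len(times), 3))
    speeds = np.zeros(n_cells)
    starts: list[tuple[int, int]] = []
    streams = np.random.SeedSequence(cfg.seed).spawn(n_cells)
    sd = cfg.speed_cv * cfg.mean_speed
    for i in range(n_cells):
        rng = np.random.default_rng(streams[i])
        if cfg.mean_speed == 0:
            speed = 0.0
        elif sd == 0:
            speed = cfg.mean_speed
        else:
            speed = -1.0
            while speed <= 0:
                speed = rng.normal(cfg.mean_speed, sd)
        speeds[i] = speed
        eid, pidx = refs[int(rng.integers(len(refs)))]
        starts.append((eid, pidx))
        s = float(eng.cum[eid][pidx])
        orient = 1 if rng.random() < 0.5 else -1
        positions[i, 0] = eng.position(eid, s)
        if speed == 0.0:
            positions[i, 1:] = positions[i, 0]
            continue
        t = 0.0
        for j in range(1, len(times)):
            t_target = times[j]
            while True:
                L = eng.length[eid]
                dist_to_end = (L - s) if orient == 1 else s
                t_vertex = t + dist_to_end / speed
                if t_vertex >= t_target - 1e-12:
                    s += orient * speed * (t_target - t)
                    s = float(np.clip(s, 0.0, L))
                    t = t_target
                    break
                t = t_vertex
                end = 1 if orient == 1 else 0
                cands, cumprobs = eng.transition(eid, end)
                if not cands:
                    orient = -orient  # dead end: reverse along the segment
                    s = L if end == 1 else 0.0
                    continue
                if len(cands) == 1:
                    k = 0
                else:
                    k = int(np.searchsorted(cumprobs, rng.random()))
                    k = min(k, len(cands) - 1)
                eid, new_end = cands[k]
                orient = 1 if new_end == 0 else -1
                s = 0.0 if new_end == 0 else eng.length[eid]
            positions[i, j] = eng.position(eid, s)
    return TrackSet(times, positions, speeds, starts)


def estimate_cm(tracks: TrackSet, T: float | None = None) -> MotilityResult:
    """MSD curve and coefficient of motility ``Cm = MSD(T) / (6 T)``.

    ``T`` defaults to the final sample time; it must be one of the sampled
    times.  The average slope of the MSD curve is taken between times 0
    and ``T``, matching the estimator used on the one-hour simulations.
    """
    times = tracks.times
    if T is None:
        T = float(times[-1])
    hits = np.isclose(times, T)
    if not hits.any():
        raise ValueError(f"T={T} is not a sample time")
    disp = tracks.positions - tracks.positions[:, :1, :]
    msd = np.mean(np.sum(disp**2, axis=2), axis=0)
    cm = float(msd[int(np.argmax(hits))] / (6.0 * T))
    return MotilityResult(times, msd, cm, tracks.n_cells, float(T))


def spider_tracks(tracks: TrackSet, n: int = 20) -> pd.DataFrame:
    """First ``n`` tracks (by cell id) translated to a common origin.

    The normalized-start representation used for spider plots of
    migration paths.
    """
    df = tracks.to_dataframe()
    df = df[df.cell_id < n].copy()
    for c, axis in zip(("x", "y", "z"), range(3)):
        origins = df.cell_id.map(
            lambda i: tracks.positions[i, 0, axis])
        df[c] = df[c] - origins
    return df
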