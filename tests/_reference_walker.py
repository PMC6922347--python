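"""Independent minimal network walker used as a simulation oracle.

Implements the same motility model as the main engine -- constant per-cell
speed, cos^4 turning-angle branch weights with a 0.001 floor for backward
turns, reversal at dead ends, 5 um chord directions -- but as a plain
stepwise event loop over polyline vertices with no caching, no arc-length
interpolation tables and its own random streams.  Deliberately slow and
simple so it can serve as a cross-check of the engine's mean squared
displacement curve.
"""

import numpy as np


def _chord_dir(points, from_end, chord=5.0):
    """Unit vector leaving the given polyline end along a `chord` um chord
    (target interpolated at exactly `chord` um of arc, or the far end)."""
    pts = points if from_end == 0 else points[::-1]
    acc = 0.0
    target = pts[-1, :3]
    for i in range(1, len(pts)):
        step = np.linalg.norm(pts[i, :3] - pts[i - 1, :3])
        if acc + step >= chord and step > 0:
            f = (chord - acc) / step
            target = pts[i - 1, :3] + f * (pts[i, :3] - pts[i - 1, :3])
            break
        acc += step
    v = target - pts[0, :3]
    n = np.linalg.norm(v)
    return v / n if n > 0 else None


def walk_msd(net, n_cells, duration, sample_interval, mean_speed, speed_cv,
             start_center, start_radius, seed):
    """Squared displacements of ``n_cells`` reference walks.

    Returns an array of shape (n_cells, n_samples) of squared displacement
    from each cell's start, sampled every ``sample_interval`` minutes.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(start_center, dtype=float)
    edges = {e.id: e.points.copy() for e in net.edges.values()}
    ends = {e.id: (e.v0, e.v1) for e in net.edges.values()}
    incident = {v: [] for v in net.vertices}
    for eid, (v0, v1) in ends.items():
        incident[v0].append((eid, 0))
        incident[v1].append((eid, 1))

    starts = []
    for eid, pts in edges.items():
        for i, p in enumerate(pts):
            if np.linalg.norm(p[:3] - center) <= start_radius:
                starts.append((eid, i))
    starts.sort()
    if not starts:
        raise ValueError("empty start sphere")

    times = np.arange(sample_interval, duration + 1e-9, sample_interval)
    out = np.zeros((n_cells, len(times)))
    for c in range(n_cells):
        speed = mean_speed
        if speed_cv > 0:
            speed = -1.0
            while speed <= 0:
                speed = rng.normal(mean_speed, speed_cv * mean_speed)
        eid, idx = starts[rng.integers(len(starts))]
        forward = rng.random() < 0.5  # toward increasing polyline index
        pos = edges[eid][idx, :3].copy()
        origin = pos.copy()
        t = 0.0
        sample_i = 0
        while sample_i < len(times):
            pts = edges[eid]
            nxt_idx = idx + 1 if forward else idx - 1
            if 0 <= nxt_idx < len(pts):
                seg = pts[nxt_idx, :3] - pos
                seg_len = np.linalg.norm(seg)
                dt = seg_len / speed
                while sample_i < len(times) and t + dt >= times[sample_i] - 1e-12:
                    frac = (times[sample_i] - t) * speed / seg_len if seg_len > 0 else 0.0
                    p = pos + frac * seg
                    out[c, sample_i] = np.sum((p - origin) ** 2)
                    sample_i += 1
                t += dt
                pos = pts[nxt_idx, :3].copy()
                idx = nxt_idx
                continue
            # at a polyline end: choose the next branch
            end = 1 if forward else 0
            vid = ends[eid][end]
            options = [(k, ke) for (k, ke) in incident[vid] if (k, ke) != (eid, end)]
            if not options:
                forward = not forward  # dead end: reverse along the edge
                continue
            # junction-directed incoming vector: the chord leaving this end
            # points back into the edge, so negate it
            back = _chord_dir(pts, end)
            v_in = -back if back is not None else None
            weights = []
            for k, ke in options:
                v_out = _chord_dir(edges[k], ke)
                if v_in is None or v_out is None:
                    weights.append(1.0)
                    continue
                cos = float(np.dot(v_in, v_out))
                weights.append(cos**4 if cos > 0 else 0.001)
            weights = np.array(weights) / np.sum(weights)
            k = rng.choice(len(options), p=weights)
            eid, new_end = options[k]
            forward = new_end == 0
            idx = 0 if forward else len(edges[eid]) - 1
            pos = edges[eid][idx, :3].copy()
    return out, times
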