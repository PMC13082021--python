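"""Filament geometry: spline resampling, distance cleaning, half-set
splitting, barrel-axis fitting and diameter/length profiles.

The operations mirror the standard filament subtomogram-averaging workflow:
manual traces are oversampled every 4 nm along an arc-length parameterized
cubic spline with the particle Z axis along the filament and a randomized
in-plane angle; particle lists are cleaned with an 8 nm minimum distance; and
FSC half-sets are split at the midpoint of each filament so overlapping
neighbor particles never straddle the two halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, interp1d

from .errors import InsufficientGeometryError, InvalidTraceError, NonContiguousLabelsError
from .particles import FilamentTrace, ParticleSet, rotation_from_tangent

#: Oversampling interval along the spline (nm).
DEFAULT_STEP = 4.0
#: Minimum inter-particle distance used for cleaning (nm).
DEFAULT_MIN_DIST = 8.0


def _arc_spline(trace: FilamentTrace, tol: float = 1e-3):
    """Natural cubic spline through the control points, reparameterized by
    arc length via dense numeric integration (refined to ``tol`` nm)."""
    pts = trace.control_points
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    spl = CubicSpline(chord, pts, bc_type="natural")
    # integrate |dP/dt| on a progressively refined grid until the total
    # length is stable to tol
    n = max(64, 8 * len(pts))
    prev = None
    for _ in range(12):
        t = np.linspace(chord[0], chord[-1], n + 1)
        speed = np.linalg.norm(spl(t, 1), axis=1)
        seg = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0 * np.diff(t))])
        total = seg[-1]
        if prev is not None and abs(total - prev) < tol:
            break
        prev = total
        n *= 2
    s_of_t = interp1d(t, seg, kind="linear", assume_sorted=True)
    t_of_s = interp1d(seg, t, kind="linear", assume_sorted=True)
    return spl, float(seg[-1]), t_of_s


def resample_spline(
    trace: FilamentTrace,
    step: float = DEFAULT_STEP,
    seed: int | None = 0,
) -> ParticleSet:
    """Oversample a trace every ``step`` nm along an arc-length spline.

    Particles sit at s = 0, step, 2·step, … ≤ total length. Each carries a
    proper rotation whose third basis vector is the local tangent and whose
    in-plane angle is drawn from a seeded uniform distribution
    (``seed=None`` sets the in-plane angle to zero).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if not isinstance(trace, FilamentTrace):
        raise InvalidTraceError("resample_spline expects a FilamentTrace")
    spl, total, t_of_s = _arc_spline(trace)
    s = np.arange(0.0, total + 1e-9, step)
    s[-1] = min(s[-1], total)
    t = np.asarray(t_of_s(s), dtype=float)
    pos = spl(t)
    tan = spl(t, 1)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    if seed is None:
        psis = np.zeros(len(s))
    else:
        psis = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi, size=len(s))
    R = np.stack([rotation_from_tangent(tan[i], psis[i]) for i in range(len(s))])
    return ParticleSet(
        positions=pos,
        arc_length=s,
        filament_id=np.full(len(s), trace.filament_id, dtype=object),
        orientations=R,
    )


def resample_traces(
    traces: list[FilamentTrace], step: float = DEFAULT_STEP, seed: int = 0
) -> ParticleSet:
    """Resample several traces with independent in-plane angle substreams."""
    from .particles import concat

    streams = np.random.SeedSequence(seed).spawn(len(traces))
    return concat(
        [
            resample_spline(tr, step=step, seed=int(ss.generate_state(1)[0] % (2**31)))
            for tr, ss in zip(traces, streams)
        ]
    )


def clean_by_distance(ps: ParticleSet, min_dist: float = DEFAULT_MIN_DIST) -> ParticleSet:
    """Greedy distance cleaning: keep a particle iff it is ≥ ``min_dist`` nm
    from every already-kept particle, scanning in stored order.

    Deterministic and idempotent; output order is the input order.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be > 0")
    pos = ps.positions
    kept: list[int] = []
    kept_pos = np.empty((0, 3))
    for i in range(len(ps)):
        if len(kept) == 0 or np.min(np.linalg.norm(kept_pos - pos[i], axis=1)) >= min_dist:
            kept.append(i)
            kept_pos = np.vstack([kept_pos, pos[i]])
    return ps.subset(np.asarray(kept, dtype=int))


def split_halfsets(ps: ParticleSet) -> ParticleSet:
    """Tag half-sets A/B at the midpoint of each filament.

    Per filament, the particles with arc position below the median rank go to
    half A (ties give the extra particle to A), the rest to B, so the halves
    are contiguous arc intervals and |#A − #B| ≤ 1.
    """
    out = ps.copy()
    halfset = np.empty(len(ps), dtype=object)
    for _, idx in ps.filaments():
        order = idx[np.argsort(ps.arc_length[idx], kind="stable")]
        n = len(order)
        n_a = (n + 1) // 2
        halfset[order[:n_a]] = "A"
        halfset[order[n_a:]] = "B"
    out.halfset = halfset
    return out


@dataclass
class BarrelAxis:
    """Axis of a multi-filament barrel: a running-centroid polyline.

    ``t`` are axial coordinates (projections onto the principal direction,
    relative to the global centroid), ``points`` the smoothed centroids.
    """

    direction: np.ndarray          # global principal direction (unit)
    origin: np.ndarray             # global centroid
    t: np.ndarray                  # (m,) window centers, increasing
    points: np.ndarray             # (m, 3) running centroids

    def axial_coord(self, positions: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(positions) - self.origin) @ self.direction

    def point_at(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(np.atleast_1d(t), self.t[0], self.t[-1])
        out = np.column_stack(
            [np.interp(t, self.t, self.points[:, k]) for k in range(3)]
        )
        return out

    def direction_at(self, t: np.ndarray) -> np.ndarray:
        """Local axis direction from the polyline gradient (unit vectors)."""
        t = np.clip(np.atleast_1d(t), self.t[0], self.t[-1])
        if len(self.t) < 2:
            d = np.tile(self.direction, (len(t), 1))
            return d
        grads = np.gradient(self.points, self.t, axis=0)
        d = np.column_stack([np.interp(t, self.t, grads[:, k]) for k in range(3)])
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return d

    def radial_distance(self, positions: np.ndarray) -> np.ndarray:
        """Perpendicular distance of each position to the local axis."""
        positions = np.atleast_2d(positions)
        tc = self.axial_coord(positions)
        a = self.point_at(tc)
        d = self.direction_at(tc)
        rel = positions - a
        perp = rel - (np.sum(rel * d, axis=1, keepdims=True)) * d
        return np.linalg.norm(perp, axis=1)


def fit_barrel_axis(ps: ParticleSet, window: float = 40.0) -> BarrelAxis:
    """Fit the barrel axis as a running centroid along the principal direction.

    Requires at least 3 filaments (a single filament does not constrain a
    barrel axis). Windows of ``window`` nm, centered every window/2, are
    averaged; window centers with no particles are dropped.
    """
    n_fil = len({fid for fid, _ in ps.filaments()})
    if n_fil < 3:
        raise InsufficientGeometryError(f"need >= 3 filaments, got {n_fil}")
    pos = ps.positions
    origin = pos.mean(axis=0)
    rel = pos - origin
    # principal direction of the point cloud = barrel axis direction
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    direction = vt[0]
    if direction @ np.array([0.0, 0.0, 1.0]) < 0:
        direction = -direction
    t = rel @ direction
    # snap to 1e-6 nm so numerically identical axial layers cannot be split
    # by a window boundary falling between their rounding errors
    t = np.round(t, 6)
    lo, hi = t.min(), t.max()
    centers = np.arange(lo, hi + 1e-9, window / 2.0)
    pts, kept = [], []
    for c in centers:
        mask = (t >= c - window / 2.0) & (t <= c + window / 2.0)
        if mask.sum() == 0:
            continue
        pts.append(pos[mask].mean(axis=0))
        kept.append(c)
    return BarrelAxis(
        direction=direction,
        origin=origin,
        t=np.asarray(kept),
        points=np.asarray(pts),
    )


@dataclass
class DiameterProfile:
    """Binned diameter profile along a barrel axis.

    ``diameter`` = 2 × mean perpendicular distance of member particles to the
    fitted axis (an axis-to-particle-center convention; see docs/methods.md).
    Bins are half-open [start, start+bin) on the axial coordinate.
    """

    bin_start: np.ndarray
    bin_width: float
    diameter: np.ndarray
    n: np.ndarray
    majority_label: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"s": self.bin_start, "diameter": self.diameter, "n": self.n}
        )
        if self.majority_label is not None:
            df["label"] = self.majority_label
        return df


def diameter_profile(
    ps: ParticleSet, axis: BarrelAxis, bin: float = 10.0
) -> DiameterProfile:
    """Per-bin barrel diameter: 2 × mean radial distance to the axis.

    Empty bins are omitted. When the particle set carries class labels, each
    bin records the majority label of its member particles.
    """
    if bin <= 0:
        raise ValueError("bin must be > 0")
    t = axis.axial_coord(ps.positions)
    r = axis.radial_distance(ps.positions)
    lo = np.floor(t.min() / bin) * bin
    idx = np.floor((t - lo) / bin).astype(int)
    starts, diams, counts, labs = [], [], [], []
    for b in np.unique(idx):
        mask = idx == b
        starts.append(lo + b * bin)
        diams.append(2.0 * r[mask].mean())
        counts.append(int(mask.sum()))
        if ps.labels is not None:
            vals, cnt = np.unique(ps.labels[mask].astype(str), return_counts=True)
            labs.append(vals[np.argmax(cnt)])
    return DiameterProfile(
        bin_start=np.asarray(starts),
        bin_width=bin,
        diameter=np.asarray(diams),
        n=np.asarray(counts, dtype=int),
        majority_label=np.asarray(labs, dtype=object) if labs else None,
    )


def zone_means(profile: DiameterProfile) -> dict[str, float]:
    """Mean diameter per zone, averaging bins by their majority class label."""
    if profile.majority_label is None:
        raise ValueError("profile has no labels; pass a labeled ParticleSet")
    out: dict[str, float] = {}
    for lab in pd.unique(profile.majority_label):
        mask = profile.majority_label == lab
        out[str(lab)] = float(profile.diameter[mask].mean())
    return out


def zone_lengths(ps: ParticleSet, step: float | None = None) -> pd.DataFrame:
    """Per-filament, per-zone arc-length extents.

    Zone length = s(last particle of the zone) − s(first) + step, so a
    single-particle zone has length ``step``. Labels must be contiguous per
    filament (run ``enforce_ordering`` first); ``step`` defaults to the
    median arc spacing of the filament.

    Returns a tidy frame (filament_id, zone, length, n) — across-filament
    means are a groupby away.
    """
    if ps.labels is None:
        raise NonContiguousLabelsError("particles are unlabeled")
    rows = []
    for fid, idx in ps.filaments():
        order = idx[np.argsort(ps.arc_length[idx], kind="stable")]
        labs = ps.labels[order].astype(str)
        s = ps.arc_length[order]
        fil_step = step if step is not None else float(np.median(np.diff(s))) if len(s) > 1 else 0.0
        seen: set[str] = set()
        runs = _runs(labs)
        for lab, i0, i1 in runs:
            if lab in seen:
                raise NonContiguousLabelsError(
                    f"label {lab!r} occurs in disjoint runs on filament {fid!r}; "
                    "run enforce_ordering first"
                )
            seen.add(lab)
            rows.append(
                {
                    "filament_id": fid,
                    "zone": lab,
                    "length": s[i1] - s[i0] + fil_step,
                    "n": i1 - i0 + 1,
                }
            )
    return pd.DataFrame(rows)


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs of equal labels: list of (label, first index, last index)."""
    runs = []
    if len(labels) == 0:
        return runs
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    return runs
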