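"""Core in-memory containers: filament traces and oriented particle sets.

All coordinates are nanometres. A :class:`ParticleSet` is the common currency
between the geometry, classification and lattice modules: every particle has a
3D position, the arc-length position ``s`` along its parent filament, and an
optional proper rotation whose third basis vector is the local filament
tangent (the convention used by subtomogram-averaging packages, where the
particle Z axis points along the filament).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidTraceError

#: Tolerance on |R @ ez - tangent| enforced when orientations are created.
TANGENT_TOL = 1e-6


@dataclass(frozen=True)
class FilamentTrace:
    """A manually traced filament: ordered control points, proximal to distal.

    Parameters
    ----------
    filament_id:
        Identifier carried through to resampled particles.
    control_points:
        (n, 3) array of points in nm, ordered proximal to distal.
    polarity:
        True if the stored order runs proximal to distal (the tracing
        convention); False flips the point order on construction.
    """

    filament_id: str
    control_points: np.ndarray
    polarity: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidTraceError("control points must be an (n, 3) array")
        if not self.polarity:
            pts = pts[::-1]
        # drop consecutive duplicates rather than erroring on them
        keep = np.ones(len(pts), dtype=bool)
        if len(pts) > 1:
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
        pts = pts[keep]
        if len(pts) < 2:
            raise InvalidTraceError(
                f"trace {self.filament_id!r} has fewer than 2 distinct control points"
            )
        object.__setattr__(self, "control_points", pts)
        object.__setattr__(self, "polarity", True)

    @property
    def n_points(self) -> int:
        return len(self.control_points)


@dataclass
class ParticleSet:
    """Oriented particles on filaments.

    Attributes
    ----------
    positions : (n, 3) float array, nm
    arc_length : (n,) float array, nm — position along the parent filament
    filament_id : (n,) object array of identifiers
    orientations : (n, 3, 3) float array or None — proper rotations; column 2
        is the local filament tangent
    labels : (n,) object array or None — observed/assigned zone labels
    true_labels : (n,) object array or None — generator ground truth
    halfset : (n,) object array or None — 'A' / 'B' tags for FSC half-sets
    particle_id : (n,) int array
    """

    positions: np.ndarray
    arc_length: np.ndarray
    filament_id: np.ndarray
    orientations: np.ndarray | None = None
    labels: np.ndarray | None = None
    true_labels: np.ndarray | None = None
    halfset: np.ndarray | None = None
    particle_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        self.filament_id = np.asarray(self.filament_id, dtype=object)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if len(self.arc_length) != n or len(self.filament_id) != n:
            raise ValueError("field lengths disagree")
        if self.particle_id is None:
            self.particle_id = np.arange(n)
        else:
            self.particle_id = np.asarray(self.particle_id, dtype=int)
        for name in ("labels", "true_labels", "halfset"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=object)
                if len(v) != n:
                    raise ValueError(f"{name} length disagrees")
                setattr(self, name, v)
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            if self.orientations.shape != (n, 3, 3):
                raise ValueError("orientations must be (n, 3, 3)")

    def __len__(self) -> int:
        return len(self.positions)

    def validate_orientations(self) -> None:
        """Check orthonormality and det=+1 of every rotation matrix."""
        if self.orientations is None:
            return
        R = self.orientations
        eye = np.eye(3)
        if not np.allclose(np.einsum("nij,nkj->nik", R, R), eye, atol=1e-8):
            raise ValueError("orientations are not orthonormal")
        if not np.allclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("orientations must be proper rotations (det +1)")

    @property
    def tangents(self) -> np.ndarray | None:
        """Local filament tangent: third column of each rotation."""
        if self.orientations is None:
            return None
        return self.orientations[:, :, 2]

    def filaments(self) -> Iterator[tuple[object, np.ndarray]]:
        """Yield (filament_id, index array) per filament, preserving first-seen order."""
        seen: dict[object, list[int]] = {}
        for i, fid in enumerate(self.filament_id):
            seen.setdefault(fid, []).append(i)
        for fid, idx in seen.items():
            yield fid, np.asarray(idx, dtype=int)

    def subset(self, mask_or_index: np.ndarray) -> "ParticleSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        take = lambda v: None if v is None else v[idx]
        return ParticleSet(
            positions=self.positions[idx],
            arc_length=self.arc_length[idx],
            filament_id=self.filament_id[idx],
            orientations=take(self.orientations),
            labels=take(self.labels),
            true_labels=take(self.true_labels),
            halfset=take(self.halfset),
            particle_id=self.particle_id[idx],
        )

    def with_labels(self, labels: Sequence) -> "ParticleSet":
        out = self.copy()
        out.labels = np.asarray(list(labels), dtype=object)
        if len(out.labels) != len(self):
            raise ValueError("label length disagrees")
        return out

    def copy(self) -> "ParticleSet":
        cp = lambda v: None if v is None else v.copy()
        return ParticleSet(
            positions=self.positions.copy(),
            arc_length=self.arc_length.copy(),
            filament_id=self.filament_id.copy(),
            orientations=cp(self.orientations),
            labels=cp(self.labels),
            true_labels=cp(self.true_labels),
            halfset=cp(self.halfset),
            particle_id=self.particle_id.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Flat tabular view (orientations as ZYZ Euler angles in degrees)."""
        import warnings

        from scipy.spatial.transform import Rotation

        df = pd.DataFrame(
            {
                "particle_id": self.particle_id,
                "filament_id": self.filament_id,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "s": self.arc_length,
            }
        )
        if self.orientations is not None:
            with warnings.catch_warnings():
                # tilt ~ 0 makes rot/psi degenerate (gimbal lock); any split
                # with rot+psi preserved round-trips the matrix, which is all
                # the dialect promises
                warnings.simplefilter("ignore", UserWarning)
                eul = Rotation.from_matrix(self.orientations).as_euler("ZYZ", degrees=True)
            df["rot"], df["tilt"], df["psi"] = eul[:, 0], eul[:, 1], eul[:, 2]
        if self.labels is not None:
            df["class_label"] = self.labels
        if self.true_labels is not None:
            df["true_label"] = self.true_labels
        if self.halfset is not None:
            df["halfset"] = self.halfset
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ParticleSet":
        from scipy.spatial.transform import Rotation

        orientations = None
        if {"rot", "tilt", "psi"}.issubset(df.columns):
            eul = df[["rot", "tilt", "psi"]].to_numpy(dtype=float)
            orientations = Rotation.from_euler("ZYZ", eul, degrees=True).as_matrix()
        opt = lambda c: df[c].to_numpy(dtype=object) if c in df.columns else None
        return cls(
            positions=df[["x", "y", "z"]].to_numpy(dtype=float),
            arc_length=df["s"].to_numpy(dtype=float),
            filament_id=df["filament_id"].to_numpy(dtype=object),
            orientations=orientations,
            labels=opt("class_label"),
            true_labels=opt("true_label"),
            halfset=opt("halfset"),
            particle_id=df["particle_id"].to_numpy(dtype=int)
            if "particle_id" in df.columns
            else None,
        )


def concat(sets: Sequence[ParticleSet]) -> ParticleSet:
    """Concatenate particle sets, renumbering particle ids."""
    if not sets:
        raise ValueError("nothing to concatenate")
    has = lambda name: all(getattr(s, name) is not None for s in sets)
    cat = lambda name: np.concatenate([getattr(s, name) for s in sets]) if has(name) else None
    out = ParticleSet(
        positions=np.concatenate([s.positions for s in sets]),
        arc_length=np.concatenate([s.arc_length for s in sets]),
        filament_id=np.concatenate([s.filament_id for s in sets]),
        orientations=cat("orientations"),
        labels=cat("labels"),
        true_labels=cat("true_labels"),
        halfset=cat("halfset"),
    )
    return out


def rotation_from_tangent(tangent: np.ndarray, psi: float) -> np.ndarray:
    """Proper rotation whose third column is ``tangent``, with in-plane angle psi.

    The first two columns span the plane normal to the tangent; ``psi``
    (radians) rotates them about the tangent, implementing the randomized
    in-plane angle convention of filament subtomogram averaging.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    # pick the world axis least aligned with t as a stable reference
    ref = np.eye(3)[np.argmin(np.abs(t))]
    u = np.cross(ref, t)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    c, s = np.cos(psi), np.sin(psi)
    col0 = c * u + s * v
    col1 = -s * u + c * v
    R = np.column_stack([col0, col1, t])
    return R
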