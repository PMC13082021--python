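"""Readers and writers for the formats the pipeline touches.

Particle tables travel as RELION-dialect STAR (coordinates in nm, ZYZ Euler
angles in degrees, helical-tube id as the filament id, random-subset as the
half-set) or as plain CSV; filament traces come from IMOD ``model2point``
text (``object contour x y z`` per line) or CSV. STAR files are parsed and
written through gemmi's STAR/CIF machinery. Numeric fields round-trip at 6
significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .particles import FilamentTrace, ParticleSet

logger = logging.getLogger(__name__)

# RELION column names used for the particle dialect; extra (non-rln) tags
# carry fields RELION has no convention for.
_STAR_COLUMNS = {
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "filament_id": "_rlnHelicalTubeID",
    "halfset": "_rlnRandomSubset",
    "particle_id": "_ciliaParticleId",
    "s": "_ciliaArcLength",
    "class_label": "_ciliaZoneLabel",
    "true_label": "_ciliaTrueZoneLabel",
}
_STAR_REVERSE = {v: k for k, v in _STAR_COLUMNS.items()}
_SIG = "%.6g"


def write_particles(ps: ParticleSet, path, dialect: str = "star") -> None:
    """Write a particle set as STAR or CSV (dialect inferred from suffix if
    'auto')."""
    path = Path(path)
    if dialect == "auto":
        dialect = "star" if path.suffix.lower() == ".star" else "csv"
    df = ps.to_dataframe()
    if dialect == "csv":
        df.to_csv(path, index=False, float_format=_SIG)
        return
    if dialect != "star":
        raise ValueError(f"unknown dialect {dialect!r}")
    import gemmi

    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    tags = [_STAR_COLUMNS[c] for c in df.columns if c in _STAR_COLUMNS]
    cols = [c for c in df.columns if c in _STAR_COLUMNS]
    loop = block.init_loop("", tags)
    halfset_code = {"A": "1", "B": "2"}
    for _, row in df.iterrows():
        vals = []
        for c in cols:
            v = row[c]
            if c == "halfset":
                vals.append(halfset_code.get(v, str(v)))
            elif isinstance(v, float):
                vals.append(_SIG % v)
            else:
                vals.append(str(v))
        loop.add_row(vals)
    doc.write_file(str(path))


def read_particles(
    path, dialect: str = "auto", class_map: dict[str, str] | None = None
) -> ParticleSet:
    """Read a particle set from STAR or CSV.

    STAR Euler angles (ZYZ, degrees) are converted back to rotation
    matrices; ``_rlnRandomSubset`` 1/2 map to half-sets A/B. ``class_map``
    optionally renames class labels (e.g. numeric RELION class ids to zone
    names). Files without angle columns load orientation-less with a warning.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "star" if path.suffix.lower() == ".star" else "csv"
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "star":
        import gemmi

        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        data = {}
        for tag, name in _STAR_REVERSE.items():
            col = block.find_loop(tag)
            vals = list(col)
            if vals:
                data[name] = vals
        if not data:
            raise SchemaError(f"{path}: no recognized particle loop")
        df = pd.DataFrame(data)
        for c in ("x", "y", "z", "s", "rot", "tilt", "psi"):
            if c in df.columns:
                df[c] = pd.to_numeric(df[c])
        if "particle_id" in df.columns:
            df["particle_id"] = pd.to_numeric(df["particle_id"]).astype(int)
        if "halfset" in df.columns:
            df["halfset"] = df["halfset"].map({"1": "A", "2": "B"}).fillna(df["halfset"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    required = {"x", "y", "z", "filament_id"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing particle column(s) {sorted(missing)}")
    if "s" not in df.columns:
        df["s"] = np.nan
    if not {"rot", "tilt", "psi"}.issubset(df.columns):
        logger.warning("%s: no Euler angle columns; particles load orientation-less", path)
    if class_map and "class_label" in df.columns:
        df["class_label"] = df["class_label"].map(lambda v: class_map.get(str(v), v))
    return ParticleSet.from_dataframe(df)


def read_imod_points(path) -> list[FilamentTrace]:
    """Parse IMOD ``model2point -object`` text: ``object contour x y z`` rows.

    Points are grouped into one trace per (object, contour), in file order;
    contour numbering is 1-based in IMOD. Coordinates are taken as nm (apply
    any pixel-size scaling before or after loading).
    """
    groups: dict[tuple[int, int], list[list[float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5:
                raise SchemaError(
                    f"{path}:{ln}: expected 'object contour x y z', got {len(parts)} fields"
                )
            try:
                obj, cont = int(parts[0]), int(parts[1])
                xyz = [float(v) for v in parts[2:5]]
            except ValueError as exc:
                raise SchemaError(f"{path}:{ln}: unparseable row ({exc})") from exc
            groups.setdefault((obj, cont), []).append(xyz)
    return [
        FilamentTrace(filament_id=f"obj{obj}_cont{cont}", control_points=np.asarray(pts))
        for (obj, cont), pts in groups.items()
    ]


def read_traces_csv(path) -> list[FilamentTrace]:
    """Read traces from CSV with columns filament_id, x, y, z (nm, ordered)."""
    df = pd.read_csv(path)
    missing = {"filament_id", "x", "y", "z"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing trace column(s) {sorted(missing)}")
    traces = []
    for fid, sub in df.groupby("filament_id", sort=False):
        traces.append(
            FilamentTrace(
                filament_id=str(fid),
                control_points=sub[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
    return traces


def write_coordinates_csv(points: np.ndarray, path) -> None:
    """Write a bare (x, y, z) nm coordinate table (necklace picks etc.)."""
    pd.DataFrame(np.atleast_2d(points), columns=["x", "y", "z"]).to_csv(
        path, index=False, float_format=_SIG
    )


def read_coordinates_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing coordinate column(s) {sorted(missing)}")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def write_flatmap_csv(fm, row_assignment, path) -> None:
    """Write unrolled coordinates with row ids (u, v, row_id)."""
    pd.DataFrame(
        {"u": fm.u, "v": fm.v, "row_id": row_assignment.row_id}
    ).to_csv(path, index=False, float_format=_SIG)
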