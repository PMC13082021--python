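"""Ground-truthed synthetic data emulating the ciliary-base study conditions.

Four generators cover the four data streams the analysis modules consume:

* :func:`gen_cilium` — a nine-filament ciliary barrel whose radius follows an
  ordered zone model (proximal centriole → core centriole → boundary →
  transition zone → early axoneme), with particles every 4 nm of arc,
  Gaussian positional jitter, and uniformly flipped class labels.
* :func:`gen_necklace` — periodic rings of intramembrane particles on a
  cylinder, the ciliary-necklace lattice.
* :func:`gen_structure` / :func:`gen_crosslinks` — idealized Cα traces and
  paired search-engine cross-link tables with planted true links and decoys.
* :func:`gen_uexm` — expansion-microscopy width measurements and two-channel
  intensity profiles with a known fluorescence gap.

Every generator is deterministic given its model's seed; per-filament / per-row
substreams are spawned from one :class:`numpy.random.SeedSequence` so outputs
are reproducible under any iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidModelError
from .particles import ParticleSet, rotation_from_tangent
from .structures import StructureMap

# Zone model measured from tomograms: (name, axial length nm, barrel diameter nm).
# Lengths of the short boundary zone and the simulated early-axoneme stretch are
# free parameters of the generator (the study reports no values for them).
DEFAULT_ZONES: tuple[tuple[str, float, float], ...] = (
    ("P", 205.0, 215.0),   # proximal centriole
    ("C", 230.0, 197.0),   # core/distal centriole
    ("B", 30.0, 190.0),    # boundary (hook / distal ring region)
    ("TZ", 253.0, 169.0),  # transition zone
    ("AX", 300.0, 178.0),  # early axoneme
)


@dataclass(frozen=True)
class CiliumModel:
    """Parameters of the synthetic ciliary barrel.

    ``zones`` is an ordered proximal→distal list of (name, length nm,
    barrel diameter nm). ``smoothing_window`` (nm) smooths the stepwise
    zone radius profile so the barrel tapers continuously, as real barrels do.
    """

    zones: tuple[tuple[str, float, float], ...] = DEFAULT_ZONES
    n_filaments: int = 9
    step: float = 4.0
    label_noise: float = 0.0
    jitter_sigma: float = 0.0
    smoothing_window: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.zones) == 0:
            raise InvalidModelError("zone list must not be empty")
        for name, length, diam in self.zones:
            if length <= 0 or diam <= 0:
                raise InvalidModelError(f"zone {name!r}: length/diameter must be > 0")
        names = [z[0] for z in self.zones]
        if len(set(names)) != len(names):
            raise InvalidModelError("zone names must be unique")
        if self.n_filaments < 3:
            raise InvalidModelError("need at least 3 filaments")
        if not (0.0 <= self.label_noise <= 1.0):
            raise InvalidModelError("label_noise must be in [0, 1]")
        if self.step <= 0:
            raise InvalidModelError("step must be > 0")

    @property
    def total_length(self) -> float:
        return float(sum(z[1] for z in self.zones))

    @property
    def zone_names(self) -> list[str]:
        return [z[0] for z in self.zones]

    def zone_boundaries(self) -> np.ndarray:
        """Axial boundaries [0, b1, ..., total_length] between zones (nm)."""
        return np.concatenate([[0.0], np.cumsum([z[1] for z in self.zones])])

    def radius_profile(self, z: np.ndarray) -> np.ndarray:
        """Barrel radius at axial positions ``z`` (smoothed stepwise profile).

        The stepwise per-zone radius is averaged over a boxcar of width
        ``smoothing_window`` centred on each query position (the profile is
        extended flat beyond the two ends), giving a continuous taper.
        """
        z = np.asarray(z, dtype=float)
        bounds = self.zone_boundaries()
        radii = np.array([z_[2] / 2.0 for z_ in self.zones])
        step_radius = lambda q: radii[
            np.clip(np.searchsorted(bounds, q, side="right") - 1, 0, len(radii) - 1)
        ]
        w = self.smoothing_window
        if w <= 0:
            return step_radius(z)
        # boxcar average of the piecewise-constant profile, by quadrature on a
        # fine fixed grid (exact to the grid resolution, deterministic)
        m = 33
        offs = np.linspace(-w / 2.0, w / 2.0, m)
        samples = step_radius(z[..., None] + offs)
        return samples.mean(axis=-1)


def gen_cilium(model: CiliumModel) -> ParticleSet:
    """Generate oriented particles on a synthetic ciliary barrel.

    Filaments are straight generatrices at equally spaced azimuths; along
    each, particles are placed every ``model.step`` nm of axial arc from 0 to
    the total zone length inclusive. Each particle carries the ground-truth
    zone label of its axial position and an observed label flipped to a
    uniformly chosen *different* zone with probability ``model.label_noise``.
    Positions are perturbed by isotropic Gaussian jitter.
    """
    total = model.total_length
    n_per = int(np.floor(total / model.step)) + 1
    s = np.arange(n_per) * model.step
    bounds = model.zone_boundaries()
    zone_idx = np.clip(np.searchsorted(bounds, s, side="right") - 1, 0, len(model.zones) - 1)
    names = np.asarray(model.zone_names, dtype=object)
    radius = model.radius_profile(s)

    streams = np.random.SeedSequence(model.seed).spawn(model.n_filaments)
    sets = []
    for k in range(model.n_filaments):
        rng = np.random.default_rng(streams[k])
        phi = 2.0 * np.pi * k / model.n_filaments
        pos = np.column_stack(
            [radius * np.cos(phi), radius * np.sin(phi), s]
        )
        if model.jitter_sigma > 0:
            pos = pos + rng.normal(0.0, model.jitter_sigma, size=pos.shape)
        true_lab = names[zone_idx]
        obs_lab = true_lab.copy()
        flip = rng.random(n_per) < model.label_noise
        if flip.any() and len(model.zones) > 1:
            # flip to a uniformly chosen different zone
            shift = rng.integers(1, len(model.zones), size=int(flip.sum()))
            obs_lab[flip] = names[(zone_idx[flip] + shift) % len(model.zones)]
        psis = rng.uniform(0.0, 2.0 * np.pi, size=n_per)
        R = np.stack([rotation_from_tangent([0.0, 0.0, 1.0], p) for p in psis])
        sets.append(
            ParticleSet(
                positions=pos,
                arc_length=s.copy(),
                filament_id=np.full(n_per, f"f{k}", dtype=object),
                orientations=R,
                labels=obs_lab,
                true_labels=true_lab,
            )
        )
    from .particles import concat

    return concat(sets)


@dataclass(frozen=True)
class NecklaceModel:
    """Parameters of the synthetic ciliary-necklace lattice.

    Rows are circumferential rings on a cylinder of radius ``cylinder_radius``
    nm, separated axially by ``row_spacing`` nm, each carrying
    ``particles_per_row`` equally spaced particles at an independent random
    phase. Defaults follow the measured lattice: 7 rows, 17.5 nm pitch, and
    54 particles per row (≈17.5 nm in-row spacing on a 945 nm circumference,
    i.e. ~6 particles per microtubule doublet).
    """

    cylinder_radius: float = 945.0 / (2.0 * np.pi)
    n_rows: int = 7
    row_spacing: float = 17.5
    particles_per_row: int = 54
    noise_sigma: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise InvalidModelError("n_rows must be >= 1")
        if self.particles_per_row < 2:
            raise InvalidModelError("particles_per_row must be >= 2")
        if self.row_spacing <= 0 or self.cylinder_radius <= 0:
            raise InvalidModelError("spacing and radius must be > 0")
        if not (0.0 <= self.missing_fraction <= 1.0):
            raise InvalidModelError("missing_fraction must be in [0, 1]")


def gen_necklace(model: NecklaceModel) -> tuple[dict, np.ndarray, np.ndarray]:
    """Generate necklace particles on a cylinder.

    Returns
    -------
    params : dict
        Ground-truth cylinder parameters: axis point/direction, radius, the
        row z-positions and the model itself.
    positions : (n, 3) float array, nm
    row_ids : (n,) int array — ground-truth row index of each particle
    """
    streams = np.random.SeedSequence(model.seed).spawn(model.n_rows)
    pos_list, row_list = [], []
    R = model.cylinder_radius
    z_rows = np.arange(model.n_rows) * model.row_spacing
    for r in range(model.n_rows):
        rng = np.random.default_rng(streams[r])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        theta = phase + 2.0 * np.pi * np.arange(model.particles_per_row) / model.particles_per_row
        pts = np.column_stack(
            [R * np.cos(theta), R * np.sin(theta), np.full_like(theta, z_rows[r])]
        )
        if model.noise_sigma > 0:
            pts = pts + rng.normal(0.0, model.noise_sigma, size=pts.shape)
        if model.missing_fraction > 0:
            keep = rng.random(len(pts)) >= model.missing_fraction
            pts = pts[keep]
        pos_list.append(pts)
        row_list.append(np.full(len(pts), r, dtype=int))
    positions = np.concatenate(pos_list)
    row_ids = np.concatenate(row_list)
    params = {
        "axis_point": np.zeros(3),
        "axis_direction": np.array([0.0, 0.0, 1.0]),
        "radius": R,
        "row_z": z_rows,
        "model": model,
    }
    return params, positions, row_ids


def gen_structure(
    n_chains: int,
    n_res: int,
    rise: float = 0.38,
    chain_offset: float = 2.0,
) -> StructureMap:
    """Idealized linear Cα traces with known inter-residue distances.

    Each chain is a straight line along z with ``rise`` nm between
    consecutive residues; chains are parallel, offset by ``chain_offset`` nm
    along x. Chain *j* is protein ``PROT{j+1}`` on chain id ``A``, ``B``, ...
    Coordinates are stored in Å (the structure-mapping unit).
    """
    if n_chains < 1 or n_res < 2:
        raise InvalidModelError("need n_chains >= 1 and n_res >= 2")
    sm = StructureMap()
    for j in range(n_chains):
        chain_id = chr(ord("A") + j % 26) + ("" if j < 26 else str(j // 26))
        protein = f"PROT{j + 1}"
        for i in range(1, n_res + 1):
            xyz = np.array([j * chain_offset * 10.0, 0.0, (i - 1) * rise * 10.0])
            sm.add(protein, i, chain_id, xyz)
    return sm


@dataclass(frozen=True)
class XlSimModel:
    """Parameters of the paired cross-link search simulation.

    ``engine_detect_prob`` gives, per engine, the probability that a planted
    true link is reported; ``decoy_rate`` the per-engine probability that a
    planted decoy (a pair violating the distance cutoff) is reported.
    """

    n_true: int = 100
    n_decoy: int = 50
    cutoff: float = 35.0
    engine_detect_prob: tuple[float, float] = (0.9, 0.8)
    decoy_rate: tuple[float, float] = (0.02, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (*self.engine_detect_prob, *self.decoy_rate):
            if not (0.0 <= p <= 1.0):
                raise InvalidModelError("probabilities must be in [0, 1]")
        if self.cutoff <= 0:
            raise InvalidModelError("cutoff must be > 0")
        if self.n_true < 1:
            raise InvalidModelError("n_true must be >= 1")


#: Minimum intra-chain sequence separation for candidate link pairs.
MIN_SEQ_SEP = 3

_XL_COLUMNS = ["protein_a", "residue_a", "protein_b", "residue_b", "score", "csm_fdr"]


def _candidate_pairs(structure: StructureMap, cutoff: float):
    """Split all informative residue pairs by the distance cutoff (Å)."""
    keys = sorted(structure._coords.keys())
    near, far = [], []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            if a[0] == b[0] and abs(a[1] - b[1]) < MIN_SEQ_SEP:
                continue
            d = structure.min_distance(a, b)
            (near if d <= cutoff else far).append((a, b, d))
    return near, far


def gen_crosslinks(
    model: XlSimModel, structure: StructureMap
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate two engine result tables and a truth table.

    True links are sampled uniformly (without replacement) from residue pairs
    with Cα–Cα distance ≤ cutoff; decoys from pairs beyond it. Each engine
    reports each true link with its detection probability and each decoy with
    its decoy rate. Scores separate the populations (true links score higher)
    and CSM-FDR values sit below the conventional engine cutoffs, so the
    tables pass through engine-side filtering unless the caller tightens it.

    Returns ``(table_a, table_b, truth)``; the truth table lists every
    planted pair with an ``is_true`` flag and its ground-truth distance.
    """
    if len(structure) == 0:
        raise GenerationError("structure is empty")
    near, far = _candidate_pairs(structure, model.cutoff)
    if len(near) < model.n_true:
        raise GenerationError(
            f"only {len(near)} residue pairs satisfy the {model.cutoff} Å cutoff; "
            f"cannot plant {model.n_true} true links"
        )
    if len(far) < model.n_decoy:
        raise GenerationError(
            f"only {len(far)} residue pairs violate the cutoff; "
            f"cannot plant {model.n_decoy} decoys"
        )
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    true_pick = [near[i] for i in rng.choice(len(near), size=model.n_true, replace=False)]
    decoy_pick = (
        [far[i] for i in rng.choice(len(far), size=model.n_decoy, replace=False)]
        if model.n_decoy
        else []
    )

    def rows(picks, is_true):
        out = []
        for (pa, ra), (pb, rb), d in picks:
            out.append(
                {
                    "protein_a": pa,
                    "residue_a": ra,
                    "protein_b": pb,
                    "residue_b": rb,
                    "distance": d,
                    "is_true": is_true,
                }
            )
        return out

    truth = pd.DataFrame(rows(true_pick, True) + rows(decoy_pick, False))

    tables = []
    for e in range(2):
        erng = np.random.default_rng(np.random.SeedSequence([model.seed, 1000 + e]))
        recs = []
        for _, row in truth.iterrows():
            p = model.engine_detect_prob[e] if row.is_true else model.decoy_rate[e]
            if erng.random() >= p:
                continue
            score = erng.normal(30.0, 5.0) if row.is_true else erng.normal(12.0, 4.0)
            fdr = erng.uniform(0.0, 0.01) if row.is_true else erng.uniform(0.0, 0.05)
            recs.append(
                {
                    "protein_a": row.protein_a,
                    "residue_a": row.residue_a,
                    "protein_b": row.protein_b,
                    "residue_b": row.residue_b,
                    "score": round(float(score), 4),
                    "csm_fdr": round(float(fdr), 6),
                }
            )
        tables.append(pd.DataFrame(recs, columns=_XL_COLUMNS))
    return tables[0], tables[1], truth


def gen_uexm(
    n_widths: int = 30,
    ef: float = 4.422,
    reference: float = 250.0,
    noise_sigma: float = 0.0,
    gap: float = 274.0,
    bb_length: float = 435.0,
    ax_length: float = 400.0,
    profile_sampling: float = 2.0,
    profile_noise: float = 0.0,
    seed: int = 0,
):
    """Synthetic expansion-microscopy measurements.

    Returns ``(widths, profile)``:

    * ``widths`` — ``n_widths`` axoneme widths (nm, expanded scale) drawn from
      Normal(ef × reference, noise_sigma): the input of expansion-factor
      estimation against the 250 nm axoneme-width reference.
    * ``profile`` — an :class:`~ciliabase.uexm.IntensityProfile` on the
      expanded scale with two channels: continuous ``tubulin``, and ``gt335``
      as two rectangular pulses (basal body, then axoneme) whose half-maximum
      edges are separated by ``gap`` nm on the *corrected* scale, i.e.
      ``gap × ef`` nm as sampled. ``gap`` defaults to the transition-zone
      length seen as a polyglutamylation gap.
    """
    from .uexm import IntensityProfile

    if ef <= 0 or reference <= 0:
        raise InvalidModelError("ef and reference must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    widths = rng.normal(ef * reference, noise_sigma, size=n_widths) if noise_sigma > 0 \
        else np.full(n_widths, ef * reference)

    bb_x = bb_length * ef
    gap_x = gap * ef
    ax_x = ax_length * ef
    margin = 50.0 * ef
    total = margin + bb_x + gap_x + ax_x + margin
    pos = np.arange(0.0, total, profile_sampling)
    gt335 = np.where(
        ((pos >= margin) & (pos < margin + bb_x))
        | ((pos >= margin + bb_x + gap_x) & (pos < margin + bb_x + gap_x + ax_x)),
        1.0,
        0.0,
    )
    tubulin = np.where((pos >= margin) & (pos < total - margin), 1.0, 0.0)
    if profile_noise > 0:
        gt335 = np.clip(gt335 + rng.normal(0.0, profile_noise, size=gt335.shape), 0.0, None)
        tubulin = np.clip(tubulin + rng.normal(0.0, profile_noise, size=tubulin.shape), 0.0, None)
    profile = IntensityProfile(
        positions=pos, channels={"tubulin": tubulin, "gt335": gt335}
    )
    return widths, profile
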