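"""Residue-to-coordinate lookup for cross-link restraint mapping.

A :class:`StructureMap` resolves ``(protein, residue)`` keys to Cα
coordinates in Å. A protein may be present as several chain copies (e.g. the
many tubulin chains of a doublet microtubule); all copies are retained so
that ambiguous self-links can be scored by the minimum distance over chain
combinations, the convention for homo-oligomer cross-link mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

logger = logging.getLogger(__name__)


@dataclass
class StructureMap:
    """Mapping (protein, residue 1-based) -> one Cα coordinate per chain copy (Å)."""

    #: (protein, residue) -> list of (chain_id, xyz Å) entries, one per chain copy
    _coords: dict[tuple[str, int], list[tuple[str, np.ndarray]]] = field(
        default_factory=dict
    )

    def add(self, protein: str, residue: int, chain: str, xyz) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError("coordinate must be a finite 3-vector")
        entries = self._coords.setdefault((protein, int(residue)), [])
        # one coordinate per (protein, residue, chain): keep the first (altlocs
        # are resolved upstream)
        if any(c == chain for c, _ in entries):
            return
        entries.append((chain, xyz))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (key[0], int(key[1])) in self._coords

    def __len__(self) -> int:
        return len(self._coords)

    def coords(self, protein: str, residue: int) -> np.ndarray:
        """(k, 3) array of the residue's Cα positions over all chain copies."""
        entries = self._coords.get((protein, int(residue)))
        if not entries:
            raise KeyError((protein, residue))
        return np.stack([xyz for _, xyz in entries])

    def proteins(self) -> set[str]:
        return {p for p, _ in self._coords}

    def min_distance(self, a: tuple[str, int], b: tuple[str, int]) -> float:
        """Minimum Cα–Cα distance (Å) over all chain-copy combinations.

        For a self-link (same protein and residue) present in >= 2 chain
        copies, the distance is taken between distinct copies; with a single
        copy it is 0 by definition of identical coordinates.
        """
        ca = self.coords(*a)
        cb = self.coords(*b)
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
        if a == (b[0], int(b[1])) and len(ca) > 1:
            np.fill_diagonal(d, np.inf)
        return float(d.min())


def read_structure(path, chain_map: dict[str, str] | None = None) -> StructureMap:
    """Extract Cα coordinates from a PDB or mmCIF file.

    Parameters
    ----------
    path:
        Coordinate file readable by gemmi (PDB or mmCIF).
    chain_map:
        Author chain id -> protein identifier. Chains absent from the map are
        skipped with a logged count. ``None`` maps every chain to itself.

    Residues are keyed by author residue number (1-based). Alternate
    locations are resolved to the highest-occupancy Cα; residues with
    insertion codes are rejected with an explicit error, since the 1-based
    author numbering contract cannot represent them.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    sm = StructureMap()
    skipped_chains: dict[str, int] = {}
    missing_ca = 0
    model = st[0]
    for chain in model:
        cid = chain.name
        if chain_map is not None and cid not in chain_map:
            skipped_chains[cid] = skipped_chains.get(cid, 0) + len(chain)
            continue
        protein = chain_map[cid] if chain_map is not None else cid
        for res in chain:
            seqid = res.seqid
            if seqid.icode not in (" ", "", "\x00"):
                raise SchemaError(
                    f"residue {cid}/{seqid.num}{seqid.icode} carries an insertion "
                    "code; renumber the model to plain author numbering first"
                )
            best = None
            for atom in res:
                if atom.name != "CA":
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is None:
                missing_ca += 1
                continue
            sm.add(protein, seqid.num, cid, [best.pos.x, best.pos.y, best.pos.z])
    if skipped_chains:
        logger.warning(
            "read_structure: skipped chains not in chain_map: %s", skipped_chains
        )
    if missing_ca:
        logger.warning("read_structure: %d residues without a Cα atom", missing_ca)
    return sm
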