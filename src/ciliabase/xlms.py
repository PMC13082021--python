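"""Cross-linking mass-spectrometry interactome construction and structure
mapping.

Two search engines produce residue-level cross-link tables, each filtered at
its own CSM-FDR cutoff (1% and 5% are the conventional per-engine defaults
for a DSSO-KSTY search). The consensus — links reported by *both* engines at
identical residue-pair identity — forms the final interactome. Links are
mapped onto coordinate models as Cα–Cα distances against the 35 Å DSSO
restraint; network statistics count unique residue-pair links, proteins, and
distinct heterotypic protein-protein interactions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError
from .structures import StructureMap

logger = logging.getLogger(__name__)

#: DSSO-compatible Cα–Cα span (Å).
DEFAULT_CUTOFF = 35.0
#: Conventional per-engine CSM FDR cutoffs.
DEFAULT_FDR_A = 0.01
DEFAULT_FDR_B = 0.05

KEY_COLUMNS = ["protein_a", "residue_a", "protein_b", "residue_b"]
REQUIRED_COLUMNS = KEY_COLUMNS + ["score", "csm_fdr"]

_ISOFORM_SUFFIX = re.compile(r"-\d+$")


@dataclass(frozen=True)
class CrossLinkRecord:
    """A residue-level cross-link, canonicalized so that
    (protein_a, residue_a) ≤ (protein_b, residue_b) lexicographically."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    score: float
    csm_fdr: float
    engine: str = ""

    def key(self) -> tuple[str, int, str, int]:
        return (self.protein_a, self.residue_a, self.protein_b, self.residue_b)


def normalize_protein_id(pid: str, strip_isoform: bool = True) -> str:
    """Case-fold an accession and optionally strip an ``-N`` isoform suffix
    (engines emit different accession styles for the same protein)."""
    pid = str(pid).strip().upper()
    if strip_isoform:
        pid = _ISOFORM_SUFFIX.sub("", pid)
    return pid


def canonicalize(df: pd.DataFrame, strip_isoform: bool = True) -> pd.DataFrame:
    """Normalize ids, order each link's two sides, and coerce residue dtypes."""
    df = df.copy()
    for col in ("protein_a", "protein_b"):
        df[col] = df[col].map(lambda p: normalize_protein_id(p, strip_isoform))
    for col in ("residue_a", "residue_b"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    a = list(zip(df["protein_a"], df["residue_a"]))
    b = list(zip(df["protein_b"], df["residue_b"]))
    swap = np.array([x > y for x, y in zip(a, b)])
    if swap.any():
        for ca, cb in (("protein_a", "protein_b"), ("residue_a", "residue_b")):
            tmp = df.loc[swap, ca].copy()
            df.loc[swap, ca] = df.loc[swap, cb]
            df.loc[swap, cb] = tmp
    return df


def load_engine_table(
    path_or_df,
    engine: str,
    fdr_cutoff: float,
    strip_isoform: bool = True,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Load and filter one engine's cross-link table.

    Keeps records with ``csm_fdr <= fdr_cutoff``, canonicalizes them, and
    de-duplicates at residue-pair level keeping the best (highest) score.
    ``column_map`` renames a real engine export's columns onto the canonical
    schema (protein_a, residue_a, protein_b, residue_b, score, csm_fdr).
    Malformed residue rows are dropped with a logged count.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"engine table is missing required column(s): {missing}")
    n0 = len(df)
    for col in ("residue_a", "residue_b"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["residue_a", "residue_b"]].isna().any(axis=1) | (
        (df["residue_a"] < 1) | (df["residue_b"] < 1)
    )
    if bad.any():
        logger.warning("%s: dropped %d rows with malformed residues", engine, int(bad.sum()))
    df = df[~bad]
    df = df[df["csm_fdr"].astype(float) <= fdr_cutoff]
    df = canonicalize(df, strip_isoform=strip_isoform)
    df = (
        df.sort_values("score", ascending=False, kind="stable")
        .drop_duplicates(subset=KEY_COLUMNS, keep="first")
        .reset_index(drop=True)
    )
    df["engine"] = engine
    logger.info(
        "%s: %d records after FDR<=%.3g filtering and de-duplication (from %d rows)",
        engine, len(df), fdr_cutoff, n0,
    )
    return df


def consensus(
    a: pd.DataFrame, b: pd.DataFrame, protein_pair_level: bool = False
) -> pd.DataFrame:
    """Links reported by both engines.

    Default granularity is exact residue-pair identity (unique cross-links
    are counted at amino-acid level); ``protein_pair_level=True`` relaxes the
    match to unordered protein pairs. The result carries both engines'
    scores and is a subset of each input; the operation is commutative.
    """
    keys = ["protein_a", "protein_b"] if protein_pair_level else KEY_COLUMNS
    if protein_pair_level:
        bkeys = b[keys].drop_duplicates()
        out = a.merge(bkeys, on=keys, how="inner").copy()
        out = out.rename(columns={"score": "score_a"})
        return out.reset_index(drop=True)
    out = a.merge(
        b[KEY_COLUMNS + ["score", "csm_fdr"]],
        on=KEY_COLUMNS,
        how="inner",
        suffixes=("_a", "_b"),
    )
    return out.reset_index(drop=True)


@dataclass
class InteractionNetwork:
    """Protein-pair graph with per-edge supporting links and summary stats."""

    graph: nx.Graph
    n_unique_links: int
    n_proteins: int
    n_ppi: int

    def stats(self) -> dict[str, int]:
        return {
            "n_unique_links": self.n_unique_links,
            "n_proteins": self.n_proteins,
            "n_ppi": self.n_ppi,
        }


def network_stats(links: pd.DataFrame, include_homotypic_ppi: bool = False) -> InteractionNetwork:
    """Build the protein-interaction network and its headline counts.

    ``n_unique_links`` counts distinct residue pairs, ``n_proteins`` distinct
    protein ids on either side of any link, ``n_ppi`` distinct unordered
    pairs of *distinct* proteins (homotypic self-pairs excluded unless
    requested). Counts are invariant to record order and duplication.
    """
    uniq = links.drop_duplicates(subset=KEY_COLUMNS)
    g = nx.Graph()
    for _, row in uniq.iterrows():
        g.add_node(row.protein_a)
        g.add_node(row.protein_b)
        edge = (row.protein_a, row.protein_b)
        if g.has_edge(*edge):
            g.edges[edge]["links"].append(
                (row.protein_a, int(row.residue_a), row.protein_b, int(row.residue_b))
            )
            g.edges[edge]["n_links"] += 1
        else:
            g.add_edge(
                *edge,
                links=[(row.protein_a, int(row.residue_a), row.protein_b, int(row.residue_b))],
                n_links=1,
            )
    hetero = sum(1 for u, v in g.edges if u != v)
    homo = sum(1 for u, v in g.edges if u == v)
    return InteractionNetwork(
        graph=g,
        n_unique_links=len(uniq),
        n_proteins=g.number_of_nodes(),
        n_ppi=hetero + (homo if include_homotypic_ppi else 0),
    )


def map_links(links: pd.DataFrame, sm: StructureMap) -> pd.DataFrame:
    """Cα–Cα distances (Å) for links whose both residues resolve in ``sm``.

    A link is *mapped* iff both (protein, residue) keys are present; the
    mapped subset is typically much smaller than the full interactome, since
    coordinate models cover few proteins. Ambiguous multi-chain residues use
    the minimum distance over chain combinations.
    """
    rows = []
    for _, row in links.drop_duplicates(subset=KEY_COLUMNS).iterrows():
        a = (row.protein_a, int(row.residue_a))
        b = (row.protein_b, int(row.residue_b))
        if a not in sm or b not in sm:
            continue
        rows.append(
            {
                "protein_a": a[0], "residue_a": a[1],
                "protein_b": b[0], "residue_b": b[1],
                "distance": sm.min_distance(a, b),
            }
        )
    return pd.DataFrame(
        rows, columns=KEY_COLUMNS + ["distance"]
    )


#: Sentinel returned when no link could be mapped (fraction is undefined).
UNDEFINED = None


def restraint_satisfaction(
    distances: pd.DataFrame | np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> tuple[int, float | None]:
    """(n_mapped, fraction of mapped links with distance ≤ cutoff).

    With zero mapped links the fraction is None (undefined, not 0).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    d = distances["distance"].to_numpy() if isinstance(distances, pd.DataFrame) \
        else np.asarray(distances, dtype=float)
    n = len(d)
    if n == 0:
        return 0, UNDEFINED
    return n, float(np.mean(d <= cutoff))


def tubulin_partners(network: InteractionNetwork, tubulin_ids: set[str]) -> set[str]:
    """Proteins with at least one link to any tubulin id (tubulins excluded)."""
    if not tubulin_ids:
        raise ValueError("tubulin_ids must be nonempty")
    tubulin_ids = {normalize_protein_id(t) for t in tubulin_ids}
    partners: set[str] = set()
    for u, v in network.graph.edges:
        if u in tubulin_ids and v not in tubulin_ids:
            partners.add(v)
        elif v in tubulin_ids and u not in tubulin_ids:
            partners.add(u)
    return partners


def topology_call(
    links: pd.DataFrame,
    partner: str,
    tubulin_ids: set[str],
    residue_annotation,
) -> str:
    """Classify a tubulin partner as lumenal or exterior from its link sites.

    ``residue_annotation(protein, residue)`` must return 'lumen', 'exterior'
    or 'unknown' for tubulin-side residues (e.g. from the radial position of
    the residue in a doublet structure). The partner is called 'lumen' if all
    its tubulin-side cross-linked residues annotate lumen, 'exterior' if all
    exterior, else 'mixed'; with no informative residues, 'unknown'.
    """
    tubulin_ids = {normalize_protein_id(t) for t in tubulin_ids}
    partner = normalize_protein_id(partner)
    calls = []
    for _, row in links.iterrows():
        for side, other in (("a", "b"), ("b", "a")):
            if (
                normalize_protein_id(row[f"protein_{other}"]) == partner
                and normalize_protein_id(row[f"protein_{side}"]) in tubulin_ids
            ):
                ann = residue_annotation(row[f"protein_{side}"], int(row[f"residue_{side}"]))
                if ann in ("lumen", "exterior"):
                    calls.append(ann)
    if not calls:
        return "unknown"
    if all(c == "lumen" for c in calls):
        return "lumen"
    if all(c == "exterior" for c in calls):
        return "exterior"
    return "mixed"


def write_edge_list(network: InteractionNetwork, path) -> None:
    """Export the network as an edge-list CSV (protein_a, protein_b, n_links)."""
    rows = [
        {"protein_a": u, "protein_b": v, "n_links": data["n_links"]}
        for u, v, data in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "n_links"]).to_csv(
        path, index=False
    )
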