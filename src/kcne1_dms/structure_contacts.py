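"""Residue-level contacts between a query chain and partner chains.

Given a complex structure (PDB or mmCIF), computes for every residue of
the query chain the minimum heavy-atom distance to each partner chain
and flags contacts below a cutoff (default 5 angstroms, strict).  Used
to ask whether variation-intolerant residues of the modulatory subunit
cluster at its interfaces with the pore subunit and calmodulin.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CONTACT_CUTOFF = 5.0


def _heavy_atom_coords(chain: gemmi.Chain) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Residue numbers and coordinates of heavy atoms, altlocs resolved
    by highest occupancy per (residue, atom name)."""
    best: dict[tuple[int, str], tuple[float, tuple[float, float, float]]] = {}
    for residue in chain:
        seqid = residue.seqid.num
        for atom in residue:
            if atom.is_hydrogen():
                continue
            key = (seqid, atom.name)
            if key not in best or atom.occ > best[key][0]:
                best[key] = (atom.occ, (atom.pos.x, atom.pos.y, atom.pos.z))
    if not best:
        raise ValueError(f"chain {chain.name!r} has no heavy atoms")
    residues = np.array([k[0] for k in best], dtype=int)
    coords = np.array([v[1] for v in best.values()], dtype=float)
    return sorted(set(residues.tolist())), residues, coords


def load_structure(path: str | Path) -> gemmi.Structure:
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    return structure


def min_residue_distances(
    structure: gemmi.Structure,
    query_chain: str,
    partner_chains: list[str],
    cutoff: float = CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Per-residue minimum heavy-atom distances to each partner chain.

    Uses the first model only.  Returns a table indexed by query residue
    number with ``dist_<chain>`` and ``contact_<chain>`` columns plus an
    any-partner ``contact`` flag (strict ``< cutoff``).
    """
    model = structure[0]
    chains = {chain.name: chain for chain in model}
    for name in [query_chain, *partner_chains]:
        if name not in chains:
            raise KeyError(f"chain {name!r} not in structure")
    q_res, q_owner, q_coords = _heavy_atom_coords(chains[query_chain])
    out = pd.DataFrame(index=pd.Index(q_res, name="residue"))
    for partner in partner_chains:
        _, _, p_coords = _heavy_atom_coords(chains[partner])
        tree = cKDTree(p_coords)
        dist_per_atom, _ = tree.query(q_coords)
        dist = pd.Series(dist_per_atom).groupby(q_owner).min()
        out[f"dist_{partner}"] = dist.reindex(q_res).to_numpy()
        out[f"contact_{partner}"] = out[f"dist_{partner}"] < cutoff
    out["contact"] = out[[f"contact_{p}" for p in partner_chains]].any(axis=1)
    return out


def intolerance_contact_overlap(
    contacts: pd.DataFrame, intolerance: pd.DataFrame
) -> dict:
    """Counts relating contact residues to intolerant/tolerant residues.

    ``contacts`` comes from :func:`min_residue_distances`;
    ``intolerance`` from :func:`kcne1_dms.evaluate.residue_intolerance`.
    Residue indexing must agree between the two tables.
    """
    joined = intolerance.join(contacts["contact"], how="inner")
    if joined.empty:
        raise ValueError("no shared residues between contacts and intolerance")
    intolerant = joined[joined["intolerant"]]
    tolerant = joined[joined["tolerant"]]
    return {
        "n_intolerant": int(len(intolerant)),
        "n_contact": int(joined["contact"].sum()),
        "n_intolerant_in_contact": int(intolerant["contact"].sum()),
        "n_tolerant": int(len(tolerant)),
        "n_tolerant_in_contact": int(tolerant["contact"].sum()),
    }
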