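"""Amino-acid chemistry tables and ideal residue templates.

Templates are heavy-atom-only idealized residues taken from the Chemical
Component Dictionary shipped with biotite.  Each template records atom
names, elements, coordinates, the intra-residue bond graph, chi-angle atom
quadruples and, per chi, the set of atoms distal to the rotated bond.

Proline is treated as a rigid ring (zero sampled chi angles): rotating its
chi dihedrals independently would break ring closure, so its side chain is
always placed from the ideal template.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}
CANONICAL_AAS = tuple(sorted(AA1_TO_3))

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Standard chi dihedral atom quadruples (heavy atoms).  Proline: rigid, none.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "A": [],
    "G": [],
    "P": [],
    "S": [("N", "CA", "CB", "OG")],
    "C": [("N", "CA", "CB", "SG")],
    "T": [("N", "CA", "CB", "OG1")],
    "V": [("N", "CA", "CB", "CG1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

N_CHI = {aa: len(q) for aa, q in CHI_ATOMS.items()}

# Hydrogen-bond capability by residue atom name.  Backbone N is a donor and
# backbone O an acceptor for every residue.
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "R": {"NE", "NH1", "NH2"}, "N": {"ND2"}, "Q": {"NE2"}, "H": {"ND1", "NE2"},
    "K": {"NZ"}, "S": {"OG"}, "T": {"OG1"}, "W": {"NE1"}, "Y": {"OH"},
}
SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "D": {"OD1", "OD2"}, "E": {"OE1", "OE2"}, "N": {"OD1"}, "Q": {"OE1"},
    "H": {"ND1", "NE2"},
    # hydroxyls (Ser/Thr/Tyr) are modeled as donors only: with heavy-atom
    # geometry a single O cannot present both roles without double counting
}


@dataclass(frozen=True)
class ResidueTemplate:
    aa: str                      # one-letter code
    atom_names: tuple[str, ...]  # heavy atoms, backbone first
    elements: tuple[str, ...]
    coords: np.ndarray           # (n, 3) ideal coordinates
    bonds: tuple[tuple[int, int], ...]
    chi_quads: tuple[tuple[int, int, int, int], ...]
    chi_distal: tuple[np.ndarray, ...]   # boolean mask per chi: atoms rotated
    graph_dist: np.ndarray       # (n, n) intra-residue bond-graph distances

    @property
    def sidechain_indices(self) -> np.ndarray:
        return np.array([i for i, nm in enumerate(self.atom_names) if nm not in BACKBONE_ATOMS])


def _graph_distances(n: int, bonds) -> np.ndarray:
    dist = np.full((n, n), 99, dtype=int)
    np.fill_diagonal(dist, 0)
    adj = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    for src in range(n):
        # BFS truncated at depth 4 (only <=3 matters for exclusions)
        frontier = [src]
        for depth in range(1, 5):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[src, v] > depth:
                        dist[src, v] = depth
                        nxt.append(v)
            frontier = nxt
    return dist


@lru_cache(maxsize=None)
def residue_template(aa: str) -> ResidueTemplate:
    """Build the heavy-atom ideal template for a one-letter amino-acid code."""
    import biotite.structure.info as info

    if aa not in AA1_TO_3:
        raise KeyError(f"unknown amino acid code {aa!r}")
    res = info.residue(AA1_TO_3[aa])
    keep = (res.element != "H") & (res.atom_name != "OXT")
    idx_map = {}
    names, elements, coords = [], [], []
    for i in np.where(keep)[0]:
        idx_map[i] = len(names)
        names.append(str(res.atom_name[i]))
        elements.append(str(res.element[i]))
        coords.append(res.coord[i])
    bond_arr = res.bonds.as_array()
    bonds = []
    for i, j, _ in bond_arr:
        if i in idx_map and j in idx_map:
            bonds.append((idx_map[i], idx_map[j]))
    name_idx = {nm: i for i, nm in enumerate(names)}
    quads = tuple(
        tuple(name_idx[a] for a in quad) for quad in CHI_ATOMS[aa]
    )
    n = len(names)
    gdist = _graph_distances(n, bonds)
    distal_masks = []
    for quad in quads:
        _, b, c, _ = quad
        # Atoms distal to bond b-c: connected to c without passing through b.
        mask = np.zeros(n, dtype=bool)
        adj = [[] for _ in range(n)]
        for i, j in bonds:
            adj[i].append(j)
            adj[j].append(i)
        stack = [c]
        seen = {b, c}
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    mask[v] = True
                    stack.append(v)
        distal_masks.append(mask)
    return ResidueTemplate(
        aa=aa,
        atom_names=tuple(names),
        elements=tuple(elements),
        coords=np.asarray(coords, float),
        bonds=tuple(bonds),
        chi_quads=quads,
        chi_distal=tuple(distal_masks),
        graph_dist=gdist,
    )


@lru_cache(maxsize=None)
def atom_graph_dist_to(aa: str, anchor: str) -> dict[str, int]:
    """Intra-residue bond-graph distance of every atom to a named anchor atom."""
    tpl = residue_template(aa)
    ai = tpl.atom_names.index(anchor)
    return {nm: int(tpl.graph_dist[i, ai]) for i, nm in enumerate(tpl.atom_names)}
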