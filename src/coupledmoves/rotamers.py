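"""Discrete side-chain states and the ligand-conformer analog.

The packaged rotamer table is a compact, backbone-dependent set: chi-angle
means with library probabilities at a small number of (phi, psi) bins on a
10-degree grid.  A reader for externally supplied tables in the same TSV
format (``AA PHI_BIN PSI_BIN PROB CHI1..CHI4``) is provided, so a larger
backbone-dependent library can be dropped in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import chem, geometry
from .structure import AtomRecord, Pose


@dataclass(frozen=True)
class Rotamer:
    aa: str
    chis: tuple[float, ...]
    prob: float
    is_current: bool = False

    def __post_init__(self):
        if len(self.chis) != chem.N_CHI[self.aa]:
            raise ValueError(
                f"{self.aa} expects {chem.N_CHI[self.aa]} chi angles, got {len(self.chis)}"
            )
        if not (0.0 < self.prob <= 1.0):
            raise ValueError(f"rotamer probability {self.prob} outside (0, 1]")


@dataclass
class RotamerSet:
    position: tuple[str, int]
    phi: float
    psi: float
    rotamers: list[Rotamer] = field(default_factory=list)

    def by_aa(self) -> dict[str, list[Rotamer]]:
        out: dict[str, list[Rotamer]] = {}
        for r in self.rotamers:
            out.setdefault(r.aa, []).append(r)
        return out


class RotamerLibrary:
    """Backbone-dependent rotamer table with nearest-bin lookup.

    Lookup is a pure function of (aa, phi-bin, psi-bin): the query angles are
    snapped to the 10-degree grid and the nearest populated bin for that
    amino acid is used.
    """

    def __init__(self, table: dict[tuple[str, int, int], list[Rotamer]]):
        self._table = table
        self._bins_by_aa: dict[str, list[tuple[int, int]]] = {}
        for (aa, phi, psi) in table:
            self._bins_by_aa.setdefault(aa, []).append((phi, psi))

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "RotamerLibrary":
        import pandas as pd

        df = pd.read_csv(path_or_buffer, sep="\t")
        table: dict[tuple[str, int, int], list[Rotamer]] = {}
        for _, row in df.iterrows():
            aa = str(row["AA"])
            nchi = chem.N_CHI[aa]
            chis = tuple(float(row[f"CHI{k + 1}"]) for k in range(nchi))
            key = (aa, int(row["PHI_BIN"]), int(row["PSI_BIN"]))
            table.setdefault(key, []).append(Rotamer(aa, chis, float(row["PROB"])))
        for rots in table.values():
            rots.sort(key=lambda r: -r.prob)
            total = sum(r.prob for r in rots)
            if total > 1.0 + 1e-9:
                raise ValueError("rotamer probabilities exceed 1 within a bin")
        return cls(table)

    @classmethod
    def packaged(cls) -> "RotamerLibrary":
        ref = resources.files("coupledmoves.data") / "rotamer_library.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @staticmethod
    def _snap(angle: float) -> int:
        return int(round(geometry.wrap_angle(angle) / 10.0)) * 10

    def query(self, aa: str, phi: float, psi: float) -> list[Rotamer]:
        """Rotamers for `aa` at the nearest populated (phi, psi) bin."""
        if aa not in self._bins_by_aa:
            raise KeyError(f"no rotamers for amino acid {aa!r}")
        qp, qs = self._snap(phi), self._snap(psi)
        best = min(
            self._bins_by_aa[aa],
            key=lambda b: _angdist(qp, b[0]) ** 2 + _angdist(qs, b[1]) ** 2,
        )
        return list(self._table[(aa, best[0], best[1])])


def _angdist(a: float, b: float) -> float:
    return abs(geometry.wrap_angle(a - b))


_DEFAULT_PHIPSI = (-60.0, -50.0)  # helical fallback for chain termini


def backbone_dihedrals(pose: Pose, position) -> tuple[float, float]:
    """(phi, psi) at a position; nearest-bin helical fallback at termini."""
    res = pose.residue(tuple(position))
    prev_r, next_r = pose.neighbors(res.key)
    if prev_r is None or next_r is None:
        return _DEFAULT_PHIPSI
    phi = geometry.dihedral(
        prev_r.backbone["C"].coords, res.backbone["N"].coords,
        res.backbone["CA"].coords, res.backbone["C"].coords,
    )
    psi = geometry.dihedral(
        res.backbone["N"].coords, res.backbone["CA"].coords,
        res.backbone["C"].coords, next_r.backbone["N"].coords,
    )
    return phi, psi


def get_rotamers(pose: Pose, position, allowed_aas, library: RotamerLibrary) -> RotamerSet:
    """Candidate rotamers at a position for the given amino acids.

    The current side-chain conformation is always appended as an extra
    candidate (flagged ``is_current``), so the null move exists; its library
    probability is that of the nearest library rotamer of the same amino
    acid.
    """
    allowed = tuple(allowed_aas)
    if not allowed:
        raise ValueError("allowed_aas is empty")
    key = tuple(position)
    res = pose.residue(key)
    phi, psi = backbone_dihedrals(pose, key)
    rotset = RotamerSet(position=key, phi=phi, psi=psi)
    for aa in allowed:
        rotset.rotamers.extend(library.query(aa, phi, psi))
    cur_chis = tuple(res.chis)
    if len(cur_chis) == chem.N_CHI[res.aa]:
        same_aa = [r for r in rotset.rotamers if r.aa == res.aa]
        if same_aa:
            nearest = min(
                same_aa,
                key=lambda r: max(
                    (_angdist(a, b) for a, b in zip(r.chis, cur_chis)), default=0.0
                ),
            )
            prob = nearest.prob
        else:
            prob = 1.0
        rotset.rotamers.append(Rotamer(res.aa, cur_chis, prob, is_current=True))
    return rotset


def align_template(res, aa: str) -> np.ndarray:
    """Template coordinates of `aa` superposed onto a residue's N/CA/C backbone.

    The returned array is in template atom order with the backbone atoms
    pinned exactly to the residue's.  Reusable across rotamers of the same
    amino acid while the backbone is unchanged.
    """
    tpl = chem.residue_template(aa)
    names = tpl.atom_names
    bb_idx = [names.index(a) for a in ("N", "CA", "C")]
    target_bb = np.array([res.backbone[a].coords for a in ("N", "CA", "C")])
    R, t, _ = geometry.kabsch(tpl.coords[bb_idx], target_bb)
    coords = tpl.coords @ R.T + t
    for bb_name in ("N", "CA", "C"):
        coords[names.index(bb_name)] = res.backbone[bb_name].coords
    return coords


def apply_chis(aa: str, aligned_coords: np.ndarray, chis) -> np.ndarray:
    """Set each chi dihedral exactly by rotating the distal atoms about its bond."""
    tpl = chem.residue_template(aa)
    coords = aligned_coords.copy()
    for k, quad in enumerate(tpl.chi_quads):
        p = [coords[i] for i in quad]
        current = geometry.dihedral(*p)
        delta = geometry.wrap_angle(chis[k] - current)
        axis_origin = coords[quad[1]]
        axis = coords[quad[2]] - coords[quad[1]]
        mask = tpl.chi_distal[k]
        coords[mask] = geometry.rotation_about_axis(coords[mask], axis_origin, axis, delta)
    return coords


def sidechain_records(aa: str, coords: np.ndarray) -> list:
    tpl = chem.residue_template(aa)
    return [
        AtomRecord(nm, tpl.elements[i], coords[i].copy())
        for i, nm in enumerate(tpl.atom_names)
        if nm not in chem.BACKBONE_ATOMS
    ]


def build_sidechain(pose: Pose, position, rotamer: Rotamer) -> Pose:
    """Replace the side chain at `position` with `rotamer`, in place.

    The side chain is rebuilt from the ideal residue template: the template
    backbone (N, CA, C) is superposed onto the residue backbone, then each
    chi dihedral is set exactly by rotating the distal atoms about the chi
    bond.  Backbone atoms are untouched.  Returns the same pose.
    """
    key = tuple(position)
    res = pose.residue(key)
    coords = apply_chis(rotamer.aa, align_template(res, rotamer.aa), rotamer.chis)
    res.aa = rotamer.aa
    res.sidechain = sidechain_records(rotamer.aa, coords)
    return pose


@dataclass(frozen=True)
class LigandConformer:
    """Discrete ligand state exposed through the rotamer-selection interface."""

    index: int
    prob: float
    is_current: bool = False


def ligand_conformer_set(ligand) -> list[LigandConformer]:
    """Conformers with uniform prior probability; the active one is flagged."""
    n = ligand.n_conformers
    if n < 1:
        raise ValueError("ligand has no conformers")
    return [
        LigandConformer(i, 1.0 / n, is_current=(i == ligand.active_conformer))
        for i in range(n)
    ]
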