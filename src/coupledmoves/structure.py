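"""Molecular data model, PDB/SDF I/O, and design-position selection.

The mutable simulation state is a :class:`Pose`: an ordered list of protein
residues plus an optional small-molecule :class:`Ligand` carrying a discrete
conformer set and a rigid-body frame.  Only heavy atoms are modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chem, geometry


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.coords.copy(), self.altloc, self.occupancy)


@dataclass
class Residue:
    chain: str
    seqpos: int
    aa: str                               # one-letter code
    backbone: dict[str, AtomRecord]       # N, CA, C, O (primary altloc)
    sidechain: list[AtomRecord] = field(default_factory=list)
    alt_atoms: list[AtomRecord] = field(default_factory=list)  # non-primary altlocs

    def __post_init__(self):
        missing = [a for a in chem.BACKBONE_ATOMS if a not in self.backbone]
        if missing:
            raise ValueError(
                f"residue {self.chain}{self.seqpos} ({self.aa}) missing backbone atoms {missing}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.seqpos)

    def atom(self, name: str) -> AtomRecord:
        if name in self.backbone:
            return self.backbone[name]
        for a in self.sidechain:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in residue {self.chain}{self.seqpos}")

    def has_atom(self, name: str) -> bool:
        try:
            self.atom(name)
            return True
        except KeyError:
            return False

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.backbone[n] for n in chem.BACKBONE_ATOMS if n in self.backbone] + list(self.sidechain)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy])

    def sidechain_heavy_coords(self) -> np.ndarray:
        """Side-chain heavy atoms; glycine uses CA as its side-chain surrogate."""
        pts = [a.coords for a in self.sidechain if a.is_heavy]
        if not pts:
            pts = [self.backbone["CA"].coords]
        return np.array(pts)

    @property
    def chis(self) -> list[float]:
        """Side-chain chi dihedrals (degrees) recomputed from coordinates."""
        out = []
        for quad in chem.CHI_ATOMS[self.aa]:
            try:
                pts = [self.atom(n).coords for n in quad]
            except KeyError:
                break
            out.append(geometry.dihedral(*pts))
        return out

    def copy(self) -> "Residue":
        return Residue(
            self.chain, self.seqpos, self.aa,
            {n: a.copy() for n, a in self.backbone.items()},
            [a.copy() for a in self.sidechain],
            [a.copy() for a in self.alt_atoms],
        )


@dataclass
class Ligand:
    """Small molecule with a fixed topology, discrete conformers and a rigid frame."""

    atom_names: list[str]
    elements: list[str]
    bonds: list[tuple[int, int]]
    conformers: list[np.ndarray]          # each (n, 3), identical topology
    frame_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    active_conformer: int = 0
    res_name: str = "LIG"

    def __post_init__(self):
        n = len(self.atom_names)
        for k, conf in enumerate(self.conformers):
            conf = np.asarray(conf, float)
            if conf.shape != (n, 3):
                raise ValueError(f"conformer {k} has wrong atom count {conf.shape[0]} != {n}")
            self.conformers[k] = conf

    @property
    def coords(self) -> np.ndarray:
        """Active-conformer coordinates with the rigid frame applied."""
        base = self.conformers[self.active_conformer]
        return base @ self.frame_rotation.T + self.frame_translation

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def centroid(self) -> np.ndarray:
        return self.coords[self.heavy_mask()].mean(axis=0)

    def apply_rigid(self, rotation: np.ndarray, translation: np.ndarray, origin: np.ndarray):
        """Compose an extra rotation about `origin` plus a translation into the frame."""
        self.frame_rotation = rotation @ self.frame_rotation
        self.frame_translation = (
            rotation @ (self.frame_translation - origin) + origin + translation
        )

    def graph_distances(self) -> np.ndarray:
        return chem._graph_distances(len(self.atom_names), self.bonds)

    def copy(self) -> "Ligand":
        return Ligand(
            list(self.atom_names), list(self.elements), list(self.bonds),
            [c.copy() for c in self.conformers],
            self.frame_rotation.copy(), self.frame_translation.copy(),
            self.active_conformer, self.res_name,
        )


@dataclass
class Pose:
    residues: list[Residue]
    ligand: Ligand | None = None
    id: str = ""

    def __post_init__(self):
        self._index = {}
        for i, r in enumerate(self.residues):
            if r.key in self._index:
                raise ValueError(f"duplicate residue key {r.key}")
            self._index[r.key] = i

    def residue(self, key: tuple[str, int]) -> Residue:
        return self.residues[self._index[key]]

    def has_residue(self, key) -> bool:
        return tuple(key) in self._index

    def index_of(self, key) -> int:
        return self._index[tuple(key)]

    def neighbors(self, key) -> tuple[Residue | None, Residue | None]:
        """Chain neighbors (i-1, i+1) of a residue, or None at termini."""
        i = self._index[tuple(key)]
        res = self.residues[i]
        prev_r = self.residues[i - 1] if i > 0 else None
        next_r = self.residues[i + 1] if i < len(self.residues) - 1 else None
        if prev_r is not None and (prev_r.chain != res.chain or prev_r.seqpos != res.seqpos - 1):
            prev_r = None
        if next_r is not None and (next_r.chain != res.chain or next_r.seqpos != res.seqpos + 1):
            next_r = None
        return prev_r, next_r

    def sequence(self, positions=None) -> str:
        if positions is None:
            return "".join(r.aa for r in self.residues)
        keys = sorted(positions)
        return "".join(self.residue(k).aa for k in keys)

    def copy(self) -> "Pose":
        return Pose(
            [r.copy() for r in self.residues],
            self.ligand.copy() if self.ligand is not None else None,
            self.id,
        )


@dataclass
class DesignTask:
    design_positions: set[tuple[str, int]] = field(default_factory=set)
    allowed_aas: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)
    repack_positions: set[tuple[str, int]] = field(default_factory=set)

    def validate(self, pose: Pose):
        overlap = self.design_positions & self.repack_positions
        if overlap:
            raise ValueError(f"positions {sorted(overlap)} are both design and repack")
        for key in self.design_positions | self.repack_positions:
            if not pose.has_residue(key):
                raise ValueError(f"task position {key} not present in pose")

    def aas_for(self, key) -> tuple[str, ...]:
        return self.allowed_aas.get(tuple(key), chem.CANONICAL_AAS)


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def read_pdb(path, ligand_code: str | None = None, model: int = 1) -> Pose:
    """Read a PDB file into a Pose.

    HETATM records whose residue name equals `ligand_code` become the pose
    ligand (bonds inferred from interatomic distances); other unknown residue
    codes are skipped with a warning.  All altloc records are retained: the
    first-seen altloc per atom is the primary conformation, later ones land
    in ``Residue.alt_atoms``.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=model, altloc="all", extra_fields=["occupancy"])

    residues: list[Residue] = []
    ligand = None
    order = []
    groups: dict[tuple, dict] = {}
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.res_name[i]))
        if key not in groups:
            groups[key] = {"atoms": []}
            order.append(key)
        groups[key]["atoms"].append(i)

    lig_indices = None
    for chain, seqpos, res_name in order:
        idxs = groups[(chain, seqpos, res_name)]["atoms"]
        if res_name in chem.AA3_TO_1:
            aa = chem.AA3_TO_1[res_name]
            backbone: dict[str, AtomRecord] = {}
            sidechain: list[AtomRecord] = []
            alt: list[AtomRecord] = []
            seen: dict[str, str] = {}
            for i in idxs:
                name = str(arr.atom_name[i])
                elem = str(arr.element[i])
                if elem == "H":
                    continue
                alt_id = str(arr.altloc_id[i]).strip(".").strip()
                rec = AtomRecord(name, elem, arr.coord[i], alt_id, float(arr.occupancy[i]))
                if name in seen and alt_id != seen[name]:
                    alt.append(rec)
                    continue
                seen[name] = alt_id
                if name in chem.BACKBONE_ATOMS:
                    backbone[name] = rec
                elif name != "OXT":
                    sidechain.append(rec)
            try:
                residues.append(Residue(chain, seqpos, aa, backbone, sidechain, alt))
            except ValueError as exc:
                raise ValueError(str(exc)) from None
        elif ligand_code is not None and res_name == ligand_code:
            lig_indices = idxs
        else:
            warnings.warn(f"skipping unknown residue {res_name} {chain}{seqpos}")

    if lig_indices is not None:
        names = [str(arr.atom_name[i]) for i in lig_indices]
        elements = [str(arr.element[i]) for i in lig_indices]
        coords = np.array([arr.coord[i] for i in lig_indices], float)
        sub = arr[np.array(lig_indices)]
        bond_list = struc.connect_via_distances(sub)
        bonds = [(int(a), int(b)) for a, b, _ in bond_list.as_array()]
        ligand = Ligand(names, elements, bonds, [coords], res_name=ligand_code)
    elif ligand_code is not None:
        warnings.warn(f"ligand code {ligand_code} not found in {path}")

    return Pose(residues, ligand, id=str(path))


def write_pdb(pose: Pose, path) -> None:
    """Write a Pose as fixed-width PDB ATOM/HETATM records (ligand last)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if not pose.residues and pose.ligand is None:
        raise ValueError("cannot write an empty pose")
    rows = []
    for res in pose.residues:
        for a in res.atoms + res.alt_atoms:
            rows.append((res.chain, res.seqpos, chem.AA1_TO_3[res.aa], a, False))
    if pose.ligand is not None:
        lig = pose.ligand
        coords = lig.coords
        for i, name in enumerate(lig.atom_names):
            rec = AtomRecord(name, lig.elements[i], coords[i])
            rows.append(("X", 1, lig.res_name, rec, True))

    arr = struc.AtomArray(len(rows))
    arr.add_annotation("occupancy", float)
    arr.add_annotation("b_factor", float)
    arr.add_annotation("altloc_id", str)
    for i, (chain, seqpos, res_name, a, hetero) in enumerate(rows):
        arr.chain_id[i] = chain
        arr.res_id[i] = seqpos
        arr.res_name[i] = res_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = hetero
        arr.coord[i] = a.coords
        arr.occupancy[i] = a.occupancy
        arr.altloc_id[i] = a.altloc if a.altloc else ""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))
    # biotite does not emit a custom altloc annotation; patch column 17
    altlocs = [row[3].altloc for row in rows]
    if any(altlocs):
        with open(path) as fh:
            lines = fh.readlines()
        k = 0
        for i, line in enumerate(lines):
            if line.startswith(("ATOM", "HETATM")):
                tag = altlocs[k] if k < len(altlocs) else ""
                lines[i] = line[:16] + (tag or " ") + line[17:]
                k += 1
        with open(path, "w") as fh:
            fh.writelines(lines)


def read_ligand_conformers(path, res_name: str = "LIG") -> Ligand:
    """Read a multi-record SDF into a Ligand (one conformer per record)."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols = [m for m in supplier]
    if not mols or mols[0] is None:
        raise ValueError(f"no readable records in {path}")
    ref = mols[0]
    n = ref.GetNumAtoms()
    elements = [a.GetSymbol() for a in ref.GetAtoms()]
    names = _ligand_atom_names(elements)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in ref.GetBonds()]
    conformers = []
    for k, mol in enumerate(mols):
        if mol is None or mol.GetNumAtoms() != n:
            raise ValueError(f"SDF record {k} does not match the topology of record 0")
        conf = mol.GetConformer()
        conformers.append(np.array([list(conf.GetAtomPosition(i)) for i in range(n)], float))
    return Ligand(names, elements, bonds, conformers, res_name=res_name)


def _ligand_atom_names(elements) -> list[str]:
    counts: dict[str, int] = {}
    names = []
    for e in elements:
        counts[e] = counts.get(e, 0) + 1
        names.append(f"{e}{counts[e]}")
    return names


def write_ligand_conformers(ligand: Ligand, path) -> None:
    """Write the ligand conformer set as a multi-record SDF."""
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for e in ligand.elements:
        mol.AddAtom(Chem.Atom(e))
    for i, j in ligand.bonds:
        mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    m = mol.GetMol()
    writer = Chem.SDWriter(str(path))
    try:
        for conf_xyz in ligand.conformers:
            conf = Chem.Conformer(len(ligand.elements))
            for i, xyz in enumerate(conf_xyz):
                conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
            m.RemoveAllConformers()
            m.AddConformer(conf)
            writer.write(m)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Design / repack position selection
# ---------------------------------------------------------------------------

def select_design_positions(
    pose: Pose, target_atoms=None, shell: float = 6.0
) -> DesignTask:
    """Residues with a side-chain heavy atom within `shell` A of target ligand atoms.

    `target_atoms` is a set of ligand atom indices (default: all heavy ligand
    atoms).  Glycine CA counts as its side-chain surrogate.
    """
    if shell <= 0:
        raise ValueError("shell distance must be positive")
    if pose.ligand is None:
        raise ValueError("pose has no ligand")
    lig_coords = pose.ligand.coords
    if target_atoms is None:
        target_atoms = [i for i, h in enumerate(pose.ligand.heavy_mask()) if h]
    target_atoms = sorted(target_atoms)
    if not target_atoms:
        raise ValueError("target_atoms is empty")
    targets = lig_coords[np.array(target_atoms)]
    task = DesignTask()
    for res in pose.residues:
        sc = res.sidechain_heavy_coords()
        d = np.linalg.norm(sc[:, None, :] - targets[None, :, :], axis=-1)
        if d.min() <= shell:
            task.design_positions.add(res.key)
            task.allowed_aas[res.key] = chem.CANONICAL_AAS
    return task


def select_repack_neighbors(
    pose: Pose, task: DesignTask, energy, rotlib, clash_threshold: float = 5.0
) -> DesignTask:
    """Add repack positions: non-design residues clashing with any candidate rotamer.

    A residue repacks if its current side chain has repulsive energy
    > `clash_threshold` against at least one rotamer of at least one design
    position.  `energy` is an EnergyModel; `rotlib` a RotamerLibrary.
    """
    from .rotamers import build_sidechain, get_rotamers

    for dkey in sorted(task.design_positions):
        work = pose.copy()
        rotset = get_rotamers(work, dkey, task.aas_for(dkey), rotlib)
        for rot in rotset.rotamers:
            build_sidechain(work, dkey, rot)
            cand = work.residue(dkey)
            cand_xyz = np.array([a.coords for a in cand.atoms])
            cand_el = [a.element for a in cand.atoms]
            for res in pose.residues:
                if res.key in task.design_positions or res.key in task.repack_positions:
                    continue
                if not res.sidechain:
                    continue
                sc_xyz = np.array([a.coords for a in res.sidechain])
                sc_el = [a.element for a in res.sidechain]
                rep = energy.repulsion_between(cand_xyz, cand_el, sc_xyz, sc_el)
                if rep > clash_threshold:
                    task.repack_positions.add(res.key)
    task.repack_positions -= task.design_positions
    return task


def superpose_by_mapping(mobile, reference, atom_map):
    """Least-squares rigid superposition over mapped atom pairs.

    `mobile`/`reference` may be Ligands, Residues, lists of AtomRecord, or
    (n, 3) arrays.  Returns (RigidTransform, rmsd); the inputs are not
    mutated.
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    pairs = list(atom_map)
    if len(pairs) < 3:
        raise ValueError("atom_map must contain at least 3 pairs")
    mi = np.array([p[0] for p in pairs])
    ri = np.array([p[1] for p in pairs])
    R, t, rmsd = geometry.kabsch(mob[mi], ref[ri])
    return RigidTransform(R, t), rmsd


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, Ligand):
        return obj.coords
    if isinstance(obj, Residue):
        return np.array([a.coords for a in obj.atoms])
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], AtomRecord):
        return np.array([a.coords for a in obj])
    return np.atleast_2d(np.asarray(obj, float))


# ---------------------------------------------------------------------------
# Task file format: one line per position, "CHAIN SEQPOS MODE [AAS]"
# ---------------------------------------------------------------------------

def read_task_file(path) -> DesignTask:
    task = DesignTask()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"task line {line_no}: expected 'CHAIN SEQPOS MODE [AAS]'")
            chain, seqpos, mode = parts[0], int(parts[1]), parts[2].upper()
            key = (chain, seqpos)
            if mode == "DESIGN":
                task.design_positions.add(key)
                if len(parts) > 3:
                    task.allowed_aas[key] = tuple(sorted(set(parts[3].upper())))
                else:
                    task.allowed_aas[key] = chem.CANONICAL_AAS
            elif mode == "REPACK":
                task.repack_positions.add(key)
            else:
                raise ValueError(f"task line {line_no}: unknown mode {mode}")
    return task


def write_task_file(task: DesignTask, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(task.design_positions):
            aas = "".join(task.aas_for(key))
            fh.write(f"{key[0]} {key[1]} DESIGN {aas}\n")
        for key in sorted(task.repack_positions):
            fh.write(f"{key[0]} {key[1]} REPACK\n")
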