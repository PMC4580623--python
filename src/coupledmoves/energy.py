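"""Pluggable energy function with one-body / two-body decomposition.

The reference implementation is a deliberately simple all-heavy-atom score:

* soft Lennard-Jones van der Waals, ``eps * ((sigma/r)^12 - 2 (sigma/r)^6)``
  with the repulsive branch linearized below ``0.6 sigma`` so overlapping
  atoms stay finite.  The repulsive component alone (the part above the
  ``-eps`` floor inside the well) is the "clash" energy used for repack
  neighbor detection.
* a distance- and angle-dependent hydrogen-bond term between donor and
  acceptor heavy atoms (window 1.5-3.3 A, optimum 2.8 A, cosine-squared
  angular falloff about an ideal donor angle, configurable well depth).
* a rotamer self-energy ``-ln(p)`` from the library probability of the
  nearest rotamer to the current side-chain conformation.
* per-amino-acid reference energies (20 constants, default 0).

Solvation and electrostatics are not modeled; a user-supplied callable can
be attached through ``EnergyConfig.extra_term``.  Protein-ligand pair terms
are multiplied by ``w_lig``.  Pairs within three covalent bonds of each
other are excluded from nonbonded scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .structure import Pose

_RADIUS = {"H": 1.0, "C": 1.75, "N": 1.55, "O": 1.50, "S": 1.80, "P": 1.80}
_EPS = {"H": 0.02, "C": 0.12, "N": 0.15, "O": 0.18, "S": 0.20, "P": 0.20}
_LIN_FRAC = 0.6  # repulsion linearized below this fraction of sigma


@dataclass
class EnergyConfig:
    w_lig: float = 1.0
    w_vdw: float = 1.0
    w_hbond: float = 1.0
    w_rotamer: float = 1.0
    hbond_depth: float = 2.0
    hbond_r0: float = 2.8
    hbond_window: tuple[float, float] = (1.5, 3.3)
    hbond_ideal_angle: float = 109.5
    cutoff: float = 10.0
    reference_energies: dict[str, float] = field(default_factory=dict)
    element_radius: dict[str, float] = field(default_factory=dict)
    element_eps: dict[str, float] = field(default_factory=dict)
    extra_term: object = None  # callable(pose) -> float, added to total

    def __post_init__(self):
        if self.w_lig <= 0:
            raise ValueError("w_lig must be positive")

    def radius(self, element: str) -> float:
        return self.element_radius.get(element, _RADIUS.get(element, 1.8))

    def eps(self, element: str) -> float:
        return self.element_eps.get(element, _EPS.get(element, 0.1))


@dataclass
class EnergyBreakdown:
    total: float
    one_body: dict[tuple[str, int], float]
    two_body: dict[tuple, float]
    protein_ligand: float
    ligand_by_position: dict[tuple[str, int], float] = field(default_factory=dict)

    def pair(self, i, j) -> float:
        return self.two_body.get(_pair_key(i, j), 0.0)


def _pair_key(i, j):
    return tuple(sorted((tuple(i), tuple(j))))


class EnergyModel:
    """Reference energy function bound to a config and a rotamer library."""

    def __init__(self, config: EnergyConfig | None = None, rotlib=None):
        self.config = config or EnergyConfig()
        self.rotlib = rotlib
        self._intra_cache: dict[str, tuple] = {}
        self._lj_param_cache: dict[tuple, tuple] = {}

    # -- atom-pair kernels -------------------------------------------------

    def _el_params(self, elements):
        key = tuple(elements)
        cached = self._lj_param_cache.get(key)
        if cached is None:
            cfg = self.config
            cached = (
                np.array([cfg.radius(e) for e in key]),
                np.array([cfg.eps(e) for e in key]),
            )
            self._lj_param_cache[key] = cached
        return cached

    def _lj_tables(self, el1, el2):
        r1, e1 = self._el_params(el1)
        r2, e2 = self._el_params(el2)
        sigma = r1[:, None] + r2[None, :]
        eps = np.sqrt(e1[:, None] * e2[None, :])
        return sigma, eps

    def lj_matrix(self, xyz1, el1, xyz2, el2):
        """(vdw, repulsive) energy matrices for two atom sets."""
        xyz1 = np.atleast_2d(xyz1)
        xyz2 = np.atleast_2d(xyz2)
        d = np.linalg.norm(xyz1[:, None, :] - xyz2[None, :, :], axis=-1)
        sigma, eps = self._lj_tables(el1, el2)
        r_lin = _LIN_FRAC * sigma
        d_safe = np.maximum(d, 1e-6)
        x = sigma / np.maximum(d_safe, r_lin)
        e_core = eps * (x**12 - 2.0 * x**6)
        # linear continuation below the cap radius
        slope = eps * (-12.0 / r_lin) * (_LIN_FRAC**-12 - _LIN_FRAC**-6)
        lin = e_core + slope * (d_safe - r_lin)
        vdw = np.where(d_safe < r_lin, lin, e_core)
        vdw = np.where(d > self.config.cutoff, 0.0, vdw)
        rep = np.where(d < sigma, vdw + eps, 0.0)
        return vdw, rep

    def repulsion_between(self, xyz1, el1, xyz2, el2) -> float:
        """Total repulsive ("clash") energy between two atom sets."""
        _, rep = self.lj_matrix(xyz1, el1, xyz2, el2)
        return float(rep.sum())

    def _hbond_energy(self, donors, acceptors, exclude=None) -> float:
        """donors: [(D_xyz, base_xyz, name)]; acceptors: [(A_xyz, name)].

        `exclude(donor_name, acceptor_name)` suppresses pairs within three
        covalent bonds of each other (adjacent-residue backbone atoms).
        """
        cfg = self.config
        lo, hi = cfg.hbond_window
        r0 = cfg.hbond_r0
        total = 0.0
        for d_xyz, base_xyz, d_name in donors:
            dx, dy, dz = float(d_xyz[0]), float(d_xyz[1]), float(d_xyz[2])
            bx = dx - float(base_xyz[0])
            by = dy - float(base_xyz[1])
            bz = dz - float(base_xyz[2])
            nbd = math.sqrt(bx * bx + by * by + bz * bz)
            if nbd < 1e-9:
                continue
            for a_xyz, a_name in acceptors:
                if exclude is not None and exclude(d_name, a_name):
                    continue
                ax = float(a_xyz[0]) - dx
                ay = float(a_xyz[1]) - dy
                az = float(a_xyz[2]) - dz
                r = math.sqrt(ax * ax + ay * ay + az * az)
                if r < lo or r > hi or r > cfg.cutoff:
                    continue
                if r >= r0:
                    g = 1.0 - ((r - r0) / (hi - r0)) ** 2
                else:
                    g = 1.0 - ((r - r0) / (r0 - lo)) ** 2
                cosang = -(bx * ax + by * ay + bz * az) / (nbd * r)
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                dev = math.radians(ang - cfg.hbond_ideal_angle)
                if abs(dev) >= math.pi / 2:
                    continue
                total -= cfg.hbond_depth * g * math.cos(dev) ** 2
        return total

    # -- residue helpers ---------------------------------------------------

    @staticmethod
    def _res_arrays(res):
        atoms = res.atoms
        xyz = np.array([a.coords for a in atoms])
        names = [a.name for a in atoms]
        el = [a.element for a in atoms]
        return atoms, xyz, names, el

    @staticmethod
    def _donors_acceptors(res):
        """Heavy-atom donors [(D, base)] and acceptors [A] for a residue."""
        donors, acceptors = [], []
        bb = res.backbone
        if "N" in bb and "CA" in bb and res.aa != "P":
            donors.append((bb["N"].coords, bb["CA"].coords, "N"))
        if "O" in bb and "C" in bb:
            acceptors.append((bb["O"].coords, "O"))
        don_names = chem.SIDECHAIN_DONORS.get(res.aa, set())
        acc_names = chem.SIDECHAIN_ACCEPTORS.get(res.aa, set())
        if don_names or acc_names:
            tpl = chem.residue_template(res.aa)
            adj = {}
            for i, j in tpl.bonds:
                adj.setdefault(tpl.atom_names[i], []).append(tpl.atom_names[j])
                adj.setdefault(tpl.atom_names[j], []).append(tpl.atom_names[i])
            for a in res.sidechain:
                if a.name in don_names:
                    base_name = next((n for n in adj.get(a.name, []) if res.has_atom(n)), None)
                    if base_name:
                        donors.append((a.coords, res.atom(base_name).coords, a.name))
                if a.name in acc_names:
                    acceptors.append((a.coords, a.name))
        return donors, acceptors

    @staticmethod
    def _ligand_donors_acceptors(ligand):
        coords = ligand.coords
        donors, acceptors = [], []
        adj = {}
        for i, j in ligand.bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        for i, e in enumerate(ligand.elements):
            name = ligand.atom_names[i]
            # directional chemistry: ligand O atoms accept, N atoms donate
            # (a donor needs a bonded base atom to define its geometry)
            if e == "O":
                acceptors.append((coords[i], name))
            elif e == "N":
                nbrs = adj.get(i, [])
                if nbrs:
                    donors.append((coords[i], coords[nbrs[0]], name))
        return donors, acceptors

    # -- energy components -------------------------------------------------

    def _intra_arrays(self, aa: str):
        """Cached (atom-name order, pair indices, sigma, eps) for >3-bond intra pairs."""
        cached = self._intra_cache.get(aa)
        if cached is None:
            tpl = chem.residue_template(aa)
            order = [nm for nm in chem.BACKBONE_ATOMS if nm in tpl.atom_names]
            order += [nm for nm in tpl.atom_names if nm not in chem.BACKBONE_ATOMS]
            tpl_pos = {nm: i for i, nm in enumerate(tpl.atom_names)}
            ia, ib, sig, eps = [], [], [], []
            for a in range(len(order)):
                for b in range(a + 1, len(order)):
                    ta, tb = tpl_pos[order[a]], tpl_pos[order[b]]
                    if tpl.graph_dist[ta, tb] > 3:
                        ia.append(a)
                        ib.append(b)
                        ea, eb = tpl.elements[ta], tpl.elements[tb]
                        sig.append(self.config.radius(ea) + self.config.radius(eb))
                        eps.append(math.sqrt(self.config.eps(ea) * self.config.eps(eb)))
            cached = (
                tuple(order),
                np.asarray(ia, int),
                np.asarray(ib, int),
                np.asarray(sig, float),
                np.asarray(eps, float),
            )
            self._intra_cache[aa] = cached
        return cached

    def _lj_vec(self, d, sigma, eps):
        r_lin = _LIN_FRAC * sigma
        d_safe = np.maximum(d, 1e-6)
        x = sigma / np.maximum(d_safe, r_lin)
        e_core = eps * (x**12 - 2.0 * x**6)
        slope = eps * (-12.0 / r_lin) * (_LIN_FRAC**-12 - _LIN_FRAC**-6)
        lin = e_core + slope * (d_safe - r_lin)
        out = np.where(d_safe < r_lin, lin, e_core)
        return np.where(d > self.config.cutoff, 0.0, out)

    def intra_residue_energy(self, res, xyz=None, names=None) -> float:
        """w_vdw-weighted nonbonded energy among a residue's own atoms."""
        if xyz is None:
            atoms = res.atoms
            xyz = np.array([a.coords for a in atoms])
            names = [a.name for a in atoms]
        order, ia, ib, sig, eps = self._intra_arrays(res.aa)
        if tuple(names) == order:
            if ia.size == 0:
                return 0.0
            d = np.linalg.norm(xyz[ia] - xyz[ib], axis=1)
            return self.config.w_vdw * float(self._lj_vec(d, sig, eps).sum())
        # slow path for incomplete residues (e.g. parsed structures)
        tpl = chem.residue_template(res.aa)
        tpl_idx = {nm: i for i, nm in enumerate(tpl.atom_names)}
        el = [tpl.elements[tpl_idx[nm]] if nm in tpl_idx else "C" for nm in names]
        vdw, _ = self.lj_matrix(xyz, el, xyz, el)
        e_intra = 0.0
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                ta, tb = tpl_idx.get(names[a]), tpl_idx.get(names[b])
                if ta is None or tb is None:
                    continue
                if tpl.graph_dist[ta, tb] > 3:
                    e_intra += vdw[a, b]
        return self.config.w_vdw * e_intra

    def one_body(self, pose: Pose, key) -> float:
        res = pose.residue(tuple(key))
        e = self.intra_residue_energy(res)
        e += self.config.w_rotamer * self.rotamer_self_energy(pose, key)
        e += self.config.reference_energies.get(res.aa, 0.0)
        return e

    def rotamer_self_energy(self, pose: Pose, key) -> float:
        """-ln(prob) of the nearest library rotamer to the current chis."""
        res = pose.residue(tuple(key))
        if chem.N_CHI[res.aa] == 0 or self.rotlib is None:
            return 0.0
        from .geometry import wrap_angle
        from .rotamers import backbone_dihedrals

        phi, psi = backbone_dihedrals(pose, tuple(key))
        rots = self.rotlib.query(res.aa, phi, psi)
        cur = res.chis
        if len(cur) != chem.N_CHI[res.aa]:
            return 0.0

        def chi_dist(r):
            return max(abs(wrap_angle(a - b)) for a, b in zip(r.chis, cur))

        nearest = min(rots, key=chi_dist)
        return -math.log(nearest.prob)

    def two_body(self, pose: Pose, key_i, key_j) -> float:
        res_i = pose.residue(tuple(key_i))
        res_j = pose.residue(tuple(key_j))
        if np.linalg.norm(
            res_i.backbone["CA"].coords - res_j.backbone["CA"].coords
        ) > self.config.cutoff + 12.0:
            return 0.0
        _, xyz_i, names_i, el_i = self._res_arrays(res_i)
        _, xyz_j, names_j, el_j = self._res_arrays(res_j)
        vdw, _ = self.lj_matrix(xyz_i, el_i, xyz_j, el_j)
        mask = self._interresidue_mask(res_i, res_j, names_i, names_j)
        e = self.config.w_vdw * float((vdw * mask).sum())
        don_i, acc_i = self._donors_acceptors(res_i)
        don_j, acc_j = self._donors_acceptors(res_j)
        adjacent = res_i.chain == res_j.chain and abs(res_i.seqpos - res_j.seqpos) == 1
        excl_ij = excl_ji = None
        if adjacent:
            if res_i.seqpos < res_j.seqpos:
                d_first = chem.atom_graph_dist_to(res_i.aa, "C")
                d_second = chem.atom_graph_dist_to(res_j.aa, "N")
                excl_ij = lambda dn, an: d_first.get(dn, 99) + 1 + d_second.get(an, 99) <= 3
                excl_ji = lambda dn, an: d_second.get(dn, 99) + 1 + d_first.get(an, 99) <= 3
            else:
                d_first = chem.atom_graph_dist_to(res_j.aa, "C")
                d_second = chem.atom_graph_dist_to(res_i.aa, "N")
                excl_ij = lambda dn, an: d_second.get(dn, 99) + 1 + d_first.get(an, 99) <= 3
                excl_ji = lambda dn, an: d_first.get(dn, 99) + 1 + d_second.get(an, 99) <= 3
        e += self.config.w_hbond * (
            self._hbond_energy(don_i, acc_j, excl_ij)
            + self._hbond_energy(don_j, acc_i, excl_ji)
        )
        return e

    @staticmethod
    def _interresidue_mask(res_i, res_j, names_i, names_j) -> np.ndarray:
        """1 where the atom pair is >3 covalent bonds apart, else 0."""
        mask = np.ones((len(names_i), len(names_j)))
        adjacent = res_i.chain == res_j.chain and abs(res_i.seqpos - res_j.seqpos) == 1
        if not adjacent:
            return mask
        if res_i.seqpos < res_j.seqpos:
            first, second = res_i, res_j
            names_f, names_s = names_i, names_j
            transpose = False
        else:
            first, second = res_j, res_i
            names_f, names_s = names_j, names_i
            transpose = True
        d_to_c = chem.atom_graph_dist_to(first.aa, "C")
        d_to_n = chem.atom_graph_dist_to(second.aa, "N")
        sub = np.ones((len(names_f), len(names_s)))
        for a, na in enumerate(names_f):
            da = d_to_c.get(na, 99)
            for b, nb in enumerate(names_s):
                if da + 1 + d_to_n.get(nb, 99) <= 3:
                    sub[a, b] = 0.0
        return sub.T if transpose else sub

    def residue_ligand(self, pose: Pose, key) -> float:
        """Unweighted residue-ligand pair energy (w_lig applied by callers)."""
        lig = pose.ligand
        if lig is None:
            return 0.0
        res = pose.residue(tuple(key))
        _, xyz, _, el = self._res_arrays(res)
        lxyz = lig.coords
        vdw, _ = self.lj_matrix(xyz, el, lxyz, lig.elements)
        e = self.config.w_vdw * float(vdw.sum())
        don_r, acc_r = self._donors_acceptors(res)
        don_l, acc_l = self._ligand_donors_acceptors(lig)
        e += self.config.w_hbond * (
            self._hbond_energy(don_r, acc_l) + self._hbond_energy(don_l, acc_r)
        )
        return e

    # -- full and partial scoring -----------------------------------------

    def score(self, pose: Pose) -> EnergyBreakdown:
        keys = [r.key for r in pose.residues]
        one = {k: self.one_body(pose, k) for k in keys}
        two: dict[tuple, float] = {}
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                e = self.two_body(pose, keys[a], keys[b])
                if e != 0.0:
                    two[_pair_key(keys[a], keys[b])] = e
        lig_map = {}
        pl = 0.0
        if pose.ligand is not None:
            for k in keys:
                e = self.residue_ligand(pose, k)
                lig_map[k] = e
                pl += e
        total = sum(one.values()) + sum(two.values()) + self.config.w_lig * pl
        if self.config.extra_term is not None:
            total += float(self.config.extra_term(pose))
        return EnergyBreakdown(total, one, two, pl, lig_map)

    def partial(self, pose: Pose, positions, include_ligand: bool = False) -> float:
        """Sum of terms touching `positions` (plus all ligand terms if flagged).

        Subtracting two partials over the same footprint gives the exact
        energy change of a move confined to that footprint.
        """
        pos = {tuple(p) for p in positions}
        keys = [r.key for r in pose.residues]
        e = sum(self.one_body(pose, k) for k in pos)
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                if keys[a] in pos or keys[b] in pos:
                    e += self.two_body(pose, keys[a], keys[b])
        if pose.ligand is not None:
            lig_keys = keys if include_ligand else sorted(pos)
            e += self.config.w_lig * sum(self.residue_ligand(pose, k) for k in lig_keys)
        return e

    def delta_energy(self, pose: Pose, change) -> float:
        """Energy change of a trial move, evaluated incrementally.

        `change` exposes ``affected(pose) -> (positions, ligand_moved)`` and
        ``apply(pose) -> None`` (in-place).  The input pose is not modified.
        """
        positions, lig_flag = change.affected(pose)
        before = self.partial(pose, positions, include_ligand=lig_flag)
        work = pose.copy()
        change.apply(work)
        after = self.partial(work, positions, include_ligand=lig_flag)
        return after - before


def score(pose: Pose, config: EnergyConfig | None = None, rotlib=None) -> EnergyBreakdown:
    """Convenience wrapper: score a pose with the reference energy function."""
    return EnergyModel(config, rotlib).score(pose)
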