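"""Deterministic synthetic test systems.

Everything here is generated programmatically: ideal-geometry alpha helices
with library-built side chains, probe ligands placed so that a chosen
mutation is favored by construction (verified by brute-force enumeration at
build time), discrete toy energy landscapes for sampler stationarity
checks, and synthetic "natural" alignments drawn from target profiles.
Fixtures use idealized bond geometry throughout, which keeps the geometric
invariants exact to tight tolerances; they do not emulate crystallographic
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem, geometry
from .energy import EnergyConfig, EnergyModel
from .rotamers import RotamerLibrary, build_sidechain, get_rotamers
from .sampler import _PivotScorer, boltzmann_select, metropolis_accept
from .structure import AtomRecord, DesignTask, Ligand, Pose, Residue

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.1


def make_helix(
    sequence: str,
    chain: str = "A",
    phi: float = -57.0,
    psi: float = -47.0,
    rotlib: RotamerLibrary | None = None,
) -> Pose:
    """Ideal-geometry alpha helix with side chains built from the rotamer library.

    Every residue gets the highest-probability rotamer for its amino acid at
    the helical backbone bin.
    """
    rotlib = rotlib or RotamerLibrary.packaged()
    n = len(sequence)
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    # NeRF backbone chain: N, CA, C triplets with phi/psi/omega dihedrals
    bb = [np.array([0.0, 0.0, 0.0]),
          np.array([_BOND_N_CA, 0.0, 0.0])]
    bb.append(
        geometry.place_atom(
            bb[0] + np.array([0.0, 1.0, 0.0]), bb[0], bb[1], _BOND_CA_C, _ANG_N_CA_C, 55.0
        )
    )
    for i in range(1, n):
        bb.append(geometry.place_atom(bb[-3], bb[-2], bb[-1], _BOND_C_N, _ANG_CA_C_N, psi))
        bb.append(geometry.place_atom(bb[-3], bb[-2], bb[-1], _BOND_N_CA, _ANG_C_N_CA, 180.0))
        bb.append(geometry.place_atom(bb[-3], bb[-2], bb[-1], _BOND_CA_C, _ANG_N_CA_C, phi))
    residues = []
    for i, aa in enumerate(sequence):
        if aa not in chem.AA1_TO_3:
            raise ValueError(f"unknown amino acid {aa!r}")
        N, CA, C = bb[3 * i], bb[3 * i + 1], bb[3 * i + 2]
        psi_here = psi if i < n - 1 else psi
        O = geometry.place_atom(N, CA, C, _BOND_C_O, _ANG_CA_C_O, psi_here + 180.0)
        backbone = {
            "N": AtomRecord("N", "N", N),
            "CA": AtomRecord("CA", "C", CA),
            "C": AtomRecord("C", "C", C),
            "O": AtomRecord("O", "O", O),
        }
        residues.append(Residue(chain, i + 1, "G", backbone))
    pose = Pose(residues, id=f"helix:{sequence}")
    for i, aa in enumerate(sequence):
        key = (chain, i + 1)
        if aa == "G":
            continue
        rotset = get_rotamers(pose, key, (aa,), rotlib)
        lib_rots = [r for r in rotset.rotamers if not r.is_current]
        top = max(lib_rots, key=lambda r: r.prob)
        build_sidechain(pose, key, top)
    return pose


# ---------------------------------------------------------------------------
# Toy protein-ligand complexes
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    sequence: str = "AAALAAA"
    pocket_index: int = 4                      # 1-based seqpos of the pocket residue
    ligand_shape: str = "hbond-probe"          # sphere-probe | two-atom-dumbbell | hbond-probe
    pocket_mutation_target: tuple | None = ((
        "A", 4), "S")                          # (position, target aa); None = no-signal fixture
    allowed_aas: tuple = ("A", "C", "D", "E", "F", "G", "I", "L", "M", "S", "V")
    probe_offset: float = 0.0                  # extra A pushed outward along the probe axis
    min_gap: float = 3.0                       # required E(target) advantage over wild type (5 kT)
    min_margin: float = 1.2                    # required advantage over every other candidate
    seed: int = 0
    energy_config: EnergyConfig = field(
        default_factory=lambda: EnergyConfig(hbond_depth=4.0)
    )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def _hbond_probe_site(pose: Pose, pocket_key, rotlib) -> np.ndarray:
    """Ideal acceptor position for the pocket serine's top hydroxyl rotamer.

    Builds a temporary Ser side chain, then places the probe 2.8 A from OG
    at the ideal donor angle, on the side pointing away from the helix.
    """
    work = pose.copy()
    rotset = get_rotamers(work, pocket_key, ("S",), rotlib)
    top = max((r for r in rotset.rotamers if not r.is_current), key=lambda r: r.prob)
    build_sidechain(work, pocket_key, top)
    res = work.residue(pocket_key)
    cb = res.atom("CB").coords
    og = res.atom("OG").coords
    axis_pts = np.array([r.backbone["CA"].coords for r in pose.residues])
    helix_center = axis_pts.mean(axis=0)
    bond = geometry.unit(og - cb)
    # directions at 109.5 deg from the CB->OG bond form a cone; take the one
    # furthest from the helix center
    ref = geometry.unit(og - helix_center)
    perp = ref - np.dot(ref, bond) * bond
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(bond, np.array([0.0, 0.0, 1.0]))
    perp = geometry.unit(perp)
    ang = np.deg2rad(180.0 - 109.5)
    direction = np.cos(ang) * bond + np.sin(ang) * perp
    return og + 2.8 * direction


def _donor_probe(pose: Pose, pocket_key, rotlib) -> Ligand:
    """Two-atom N-C donor probe at ideal geometry for an aspartate carboxylate.

    Builds the pocket aspartate's top rotamer, then places the donor N
    2.8 A from OD1 on the side away from the helix, with its base carbon at
    the ideal base-donor-acceptor angle.
    """
    work = pose.copy()
    rotset = get_rotamers(work, pocket_key, ("D",), rotlib)
    top = max((r for r in rotset.rotamers if not r.is_current), key=lambda r: r.prob)
    build_sidechain(work, pocket_key, top)
    res = work.residue(pocket_key)
    od1 = res.atom("OD1").coords
    helix_center = np.array([r.backbone["CA"].coords for r in pose.residues]).mean(axis=0)
    out = geometry.unit(od1 - helix_center)
    n_pos = od1 + 2.8 * out
    v = geometry.unit(od1 - n_pos)  # N -> acceptor direction
    w = out - np.dot(out, v) * v
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(v, np.array([0.0, 0.0, 1.0]))
    w = geometry.unit(w)
    ang = np.deg2rad(109.5)
    base = n_pos + 1.4 * (np.cos(ang) * v + np.sin(ang) * w)
    return Ligand(
        ["N1", "C1"], ["N", "C"], [(0, 1)],
        [np.array([n_pos, base])], res_name="LIG",
    )


def _sphere(center, element="C"):
    return Ligand([f"{element}1"], [element], [], [np.atleast_2d(center)], res_name="LIG")


def _dumbbell(center, direction, separation=1.5, element="C"):
    d = geometry.unit(direction) * (separation / 2.0)
    coords = np.array([center - d, center + d])
    return Ligand(
        [f"{element}1", f"{element}2"], [element, element], [(0, 1)], [coords], res_name="LIG"
    )


def make_toy_complex(spec: ToyComplexSpec, rotlib: RotamerLibrary | None = None):
    """Build a toy helix-ligand complex with a provable design ground truth.

    Returns (pose, task, notes).  `notes` records the brute-force energy of
    the best rotamer of every allowed amino acid at the pocket position.
    The build fails loudly if the intended mutation is not favored by the
    configured margins; a spec with ``pocket_mutation_target=None`` is a
    no-signal fixture and instead requires all mutations to be near-neutral.
    """
    rotlib = rotlib or RotamerLibrary.packaged()
    pose = make_helix(spec.sequence, rotlib=rotlib)
    pocket_key = ("A", spec.pocket_index)
    ca = pose.residue(pocket_key).backbone["CA"].coords
    if spec.ligand_shape == "hbond-probe":
        site = _hbond_probe_site(pose, pocket_key, rotlib)
        outward = geometry.unit(site - ca)
        pose.ligand = _sphere(site + spec.probe_offset * outward, "O")
    elif spec.ligand_shape in ("sphere-probe", "two-atom-dumbbell"):
        # place along the wild-type side chain's own direction, just outside
        # CB contact range, so only side chains with atoms past CB clash
        tip = pose.residue(pocket_key).sidechain_heavy_coords().mean(axis=0)
        outward = geometry.unit(tip - ca)
        center = ca + (5.0 + spec.probe_offset) * outward
        if spec.ligand_shape == "sphere-probe":
            pose.ligand = _sphere(center, "C")
        else:
            helix_axis = geometry.unit(
                pose.residues[-1].backbone["CA"].coords
                - pose.residues[0].backbone["CA"].coords
            )
            perp = helix_axis - np.dot(helix_axis, outward) * outward
            pose.ligand = _dumbbell(center, perp)
    else:
        raise ValueError(f"unknown ligand shape {spec.ligand_shape!r}")

    task = DesignTask(
        design_positions={pocket_key},
        allowed_aas={pocket_key: tuple(sorted(spec.allowed_aas))},
    )
    task.validate(pose)

    notes = enumerate_pocket_energies(pose, pocket_key, task.aas_for(pocket_key), rotlib,
                                      spec.energy_config)
    wt_aa = pose.residue(pocket_key).aa
    if spec.pocket_mutation_target is not None:
        target_pos, target_aa = spec.pocket_mutation_target
        if tuple(target_pos) != pocket_key:
            raise ValueError("pocket_mutation_target position must be the pocket position")
        e_target = notes[target_aa]
        if e_target > notes[wt_aa] - spec.min_gap:
            raise ValueError(
                f"fixture drift: E({target_aa})={e_target:.2f} not {spec.min_gap} below "
                f"E({wt_aa})={notes[wt_aa]:.2f}"
            )
        others = {aa: e for aa, e in notes.items() if aa not in (target_aa,)}
        runner_up = min(others.values())
        if e_target > runner_up - spec.min_margin:
            raise ValueError(
                f"fixture drift: E({target_aa})={e_target:.2f} not {spec.min_margin} below "
                f"runner-up {runner_up:.2f}"
            )
    else:
        # no-signal fixture: the ligand must contribute nothing to any mutation
        apo = pose.copy()
        apo.ligand = None
        base = enumerate_pocket_energies(apo, pocket_key, task.aas_for(pocket_key), rotlib,
                                         spec.energy_config)
        lig_part = {aa: notes[aa] - base[aa] for aa in notes}
        worst = max(abs(v) for v in lig_part.values())
        if worst > 0.1:
            raise ValueError(f"no-signal fixture: ligand contributes up to {worst:.3f} > 0.1")
    return pose, task, notes


def enumerate_pocket_energies(pose, pocket_key, allowed_aas, rotlib, energy_config):
    """Brute-force best-rotamer pivot energy for every allowed amino acid."""
    model = EnergyModel(energy_config, rotlib)
    out = {}
    for aa in allowed_aas:
        work = pose.copy()
        rotset = get_rotamers(work, pocket_key, (aa,), rotlib)
        scorer = _PivotScorer(model, work, pocket_key)
        best = None
        for r in rotset.rotamers:
            if r.aa != aa:
                continue
            build_sidechain(work, pocket_key, r)
            e = scorer.energy()
            if best is None or e < best:
                best = e
        out[aa] = best
    return out


def specificity_pair(seed: int = 0, rotlib: RotamerLibrary | None = None):
    """Native / non-native complex pair for the specificity toy benchmark.

    The wild-type pocket is an aspartate whose carboxylate accepts a
    hydrogen bond from the native ligand, a two-atom N-C donor probe placed
    at ideal geometry for the top aspartate rotamer.  The non-native ligand
    is a single-atom acceptor probe placed where only a pocket serine
    hydroxyl can donate to it, so the ground-truth specificity-switch
    mutation is D->S: each condition has its own hydrogen-bonded optimum,
    provable by enumeration.  The candidate alphabet excludes the other
    donor-capable residues that could reach the acceptor probe.  Returns
    (native_pose, nonnative_pose, task, notes).
    """
    rotlib = rotlib or RotamerLibrary.packaged()
    spec_nn = ToyComplexSpec(
        sequence="AAADAAA",
        pocket_index=4,
        ligand_shape="hbond-probe",
        pocket_mutation_target=(("A", 4), "S"),
        allowed_aas=("A", "C", "D", "E", "F", "G", "I", "L", "M", "S", "V"),
        seed=seed,
        energy_config=EnergyConfig(hbond_depth=4.0),
    )
    nonnative_pose, task, notes = make_toy_complex(spec_nn, rotlib)
    # a second, ligand-inert designable position: percent occurrence is
    # measured over unique sequences, and with a single position that
    # statistic degenerates to 1/|set|; the freely drifting bystander
    # restores residence weighting through sequence diversity, as the
    # multi-position design regions of real binding sites do
    bystander = ("A", 6)
    task.design_positions.add(bystander)
    task.allowed_aas[bystander] = task.aas_for(("A", 4))
    holo = enumerate_pocket_energies(
        nonnative_pose, bystander, task.aas_for(bystander), rotlib, spec_nn.energy_config
    )
    apo = _apo_energies(
        nonnative_pose, bystander, task.aas_for(bystander), rotlib, spec_nn.energy_config
    )
    lig_part = {aa: holo[aa] - apo[aa] for aa in holo}
    if max(abs(v) for v in lig_part.values()) > 0.1:
        raise ValueError(f"fixture drift: bystander position sees the ligand: {lig_part}")
    native_pose = nonnative_pose.copy()
    native_pose.ligand = _donor_probe(nonnative_pose, ("A", 4), rotlib)
    native_notes = enumerate_pocket_energies(
        native_pose, ("A", 4), task.aas_for(("A", 4)), rotlib, spec_nn.energy_config
    )
    native_best = min(native_notes, key=native_notes.get)
    if native_notes["S"] < native_notes[native_best] + 1.0 or native_best == "S":
        raise ValueError(
            f"fixture drift: serine is not disfavored in the native complex: {native_notes}"
        )
    return native_pose, nonnative_pose, task, notes


def _apo_energies(pose, key, allowed, rotlib, config):
    apo = pose.copy()
    apo.ligand = None
    return enumerate_pocket_energies(apo, key, allowed, rotlib, config)


def crowded_complex(seed: int = 0, rotlib: RotamerLibrary | None = None,
                    offset: float = 3.0):
    """Crowded pocket used for protocol-variant comparisons.

    Three bulky designable residues pack against a dumbbell ligand wedged
    into the pocket, so most random mutations clash while the wild-type
    arrangement fits snugly.  Returns (pose, task, energy_config).
    """
    rotlib = rotlib or RotamerLibrary.packaged()
    pose = make_helix("AAAALAAALAA", rotlib=rotlib)
    # nestle the dumbbell against the side chains of the i, i+4 pair L5/L9
    # (same helix face) so that bulky hydrophobic residues pack snugly
    # (verified below) and any smaller residue loses favorable contacts
    keys = [("A", 5), ("A", 9)]
    tips = [pose.residue(k).sidechain_heavy_coords().mean(axis=0) for k in keys]
    center = np.mean(tips, axis=0)
    axis_pts = np.array([r.backbone["CA"].coords for r in pose.residues])
    helix_axis = geometry.unit(axis_pts[-1] - axis_pts[0])
    origin = axis_pts.mean(axis=0)
    along = np.dot(center - origin, helix_axis)
    outward = geometry.unit(center - (origin + along * helix_axis))
    pose.ligand = _dumbbell(center + offset * outward, helix_axis)
    pocket_alphabet = ("A", "F", "G", "I", "L", "M", "S", "V")
    task = DesignTask(
        design_positions=set(keys),
        allowed_aas={k: pocket_alphabet for k in keys},
    )
    task.validate(pose)
    config = EnergyConfig()
    # build-time self-check: glycine must be clearly penalized at each pocket
    # position relative to the best amino acid, and the start pose must be
    # clash-free (no positive residue-ligand term)
    model = EnergyModel(config, rotlib)
    br = model.score(pose)
    worst_lig = max(br.ligand_by_position.values(), default=0.0)
    if worst_lig > 1.0:
        raise ValueError(f"fixture drift: start pose clashes with the ligand ({worst_lig:.1f})")
    for k in keys:
        notes = enumerate_pocket_energies(
            pose, k, ("A", "G", "V", "I", pose.residue(k).aa), rotlib, config
        )
        if notes["G"] - min(notes.values()) < 1.5:
            raise ValueError(f"fixture drift: glycine not penalized at {k}: {notes}")
    return pose, task, config


# ---------------------------------------------------------------------------
# Discrete toy landscapes
# ---------------------------------------------------------------------------

class DiscreteLandscape:
    """Minimal system whose 'rotamers' are states with fixed energies.

    ``run_chain`` drives the same move kernel as the sampler: at each step
    the next state is Boltzmann-selected among all states (energies relative
    to the current state), then the Metropolis-Hastings test is applied.
    Because Boltzmann selection over the full state list is an independence
    sampler from the target distribution, the Hastings correction makes the
    acceptance identically 1 and the chain samples exp(-E/kT) exactly;
    disabling it (``hastings=False``) reproduces the plain-Metropolis
    variant, whose stationary weights are exp(-2E/kT).
    """

    def __init__(self, energies):
        self.energies = np.asarray(list(energies), float)
        if self.energies.size < 1 or not np.all(np.isfinite(self.energies)):
            raise ValueError("need >= 1 finite state energies")

    def stationary(self, kT: float) -> np.ndarray:
        w = np.exp(-(self.energies - self.energies.min()) / kT)
        return w / w.sum()

    def run_chain(
        self,
        n_moves: int,
        kT: float,
        rng: np.random.Generator,
        start: int = 0,
        hastings: bool = True,
    ) -> np.ndarray:
        """Occupancy fractions over `n_moves` steps."""
        counts = np.zeros(self.energies.size)
        state = start
        for _ in range(n_moves):
            rel = self.energies - self.energies[state]
            j, _ = boltzmann_select(rel, kT, rng)
            dE = float(rel[j])
            log_h = dE / kT if hastings else 0.0
            if metropolis_accept(dE, kT, rng, log_hastings=log_h):
                state = j
            counts[state] += 1
        return counts / counts.sum()


def make_discrete_landscape(states) -> DiscreteLandscape:
    return DiscreteLandscape(states)


# ---------------------------------------------------------------------------
# Synthetic natural alignments
# ---------------------------------------------------------------------------

def make_natural_msa(profiles, n_seqs: int, seed: int = 0) -> list[str]:
    """Sequences sampled i.i.d. per column from target amino-acid profiles.

    `profiles` is a list of 20-vectors over the alphabetically ordered
    amino acids (or PositionProfile objects).
    """
    rng = np.random.default_rng(seed)
    cols = []
    for p in profiles:
        vec = np.asarray(getattr(p, "p", p), float)
        if vec.shape != (20,) or abs(vec.sum() - 1.0) > 1e-9 or np.any(vec < 0):
            raise ValueError("each profile must be a normalized 20-vector")
        cols.append(rng.choice(list(chem.CANONICAL_AAS), size=n_seqs, p=vec))
    return ["".join(col[i] for col in cols) for i in range(n_seqs)]
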