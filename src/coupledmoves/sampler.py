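"""The coupled-moves Monte Carlo protocol and the fixed-backbone baseline.

Each protein move couples a backrub backbone perturbation to a
Boltzmann-weighted choice of side-chain rotamer and (at design positions)
amino acid at the pivot residue; each ligand move couples a small rigid-body
perturbation to a Boltzmann-weighted conformer choice.  The coupled proposal
is then accepted or rejected by the Metropolis criterion at constant
temperature.  One kT (default 0.6 energy units) governs both the selection
probabilities and the acceptance test.

Protocol variants: ``sc_selection="uniform"`` replaces both selection stages
with uniform draws (Uni SC); ``backbone="fixed"`` skips the backrub
perturbation (Fix BB).  The fixed-backbone baseline packer is a separate
simulated-annealing protocol with uniform single-rotamer proposals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .backrub import BackrubMove, BackrubParams, apply_backrub, sample_backrub_angle
from .energy import EnergyModel
from .rotamers import build_sidechain, get_rotamers, ligand_conformer_set
from .structure import DesignTask, Pose


@dataclass
class SamplerConfig:
    kT: float = 0.6
    n_moves: int = 1000
    n_sims: int = 20
    p_ligand: float = 0.1
    sigma_theta: float = 4.57
    sigma_rot: float = 1.0      # degrees, ligand rigid-body rotation
    sigma_trans: float = 0.1    # Angstrom, sd of the total displacement vector
    sc_selection: str = "boltzmann"   # "boltzmann" | "uniform"
    backbone: str = "flexible"        # "flexible" | "fixed"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_ligand <= 1.0):
            raise ValueError("p_ligand must be in [0, 1]")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.n_moves < 1:
            raise ValueError("n_moves must be >= 1")
        if self.sc_selection not in ("boltzmann", "uniform"):
            raise ValueError("sc_selection must be 'boltzmann' or 'uniform'")
        if self.backbone not in ("flexible", "fixed"):
            raise ValueError("backbone must be 'flexible' or 'fixed'")


@dataclass
class MoveRecord:
    move_type: str                 # "protein" | "ligand"
    position: tuple | None
    delta_E: float
    accepted: bool
    theta: float = 0.0


@dataclass
class DesignTrace:
    design_positions: tuple
    sequences: list[str]
    move_ledger: list[MoveRecord]
    best_pose_per_sequence: dict[str, Pose]
    best_energy_per_sequence: dict[str, float]

    @property
    def acceptance_ratio(self) -> float:
        if not self.move_ledger:
            return 0.0
        return sum(m.accepted for m in self.move_ledger) / len(self.move_ledger)


@dataclass
class SequenceSet:
    design_positions: tuple
    sequences: list[str]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences):
                fh.write(f">seq_{i}\n{seq}\n")

    @classmethod
    def read_fasta(cls, path, design_positions=()) -> "SequenceSet":
        from Bio import SeqIO

        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(tuple(design_positions), seqs)


# ---------------------------------------------------------------------------
# Elementary stochastic kernels
# ---------------------------------------------------------------------------

def boltzmann_select(energies, kT: float, rng: np.random.Generator):
    """Draw an index with probability P(E_i) = exp(-E_i/kT) / sum_j exp(-E_j/kT).

    Energies are shifted by their minimum before exponentiation, so very
    large energies underflow to probability zero instead of overflowing.
    Returns (index, probability vector).
    """
    E = np.asarray(list(energies), float)
    if E.size == 0:
        raise ValueError("boltzmann_select requires a nonempty energy list")
    if not np.all(np.isfinite(E)):
        raise ValueError("boltzmann_select requires finite energies")
    w = np.exp(-(E - E.min()) / kT)
    p = w / w.sum()
    idx = int(rng.choice(E.size, p=p))
    return idx, p


def metropolis_accept(
    delta_E: float, kT: float, rng: np.random.Generator, log_hastings: float = 0.0
) -> bool:
    """Metropolis criterion: accept if dE <= 0, else with probability e^(-dE/kT).

    `log_hastings` adds a proposal-density correction (ln q(reverse) -
    ln q(forward)) for proposal schemes that are not symmetric; the default
    of 0 is the plain Metropolis test.
    """
    if not math.isfinite(delta_E):
        raise ValueError("delta_E must be finite")
    log_p = -delta_E / kT + log_hastings
    if log_p >= 0:
        return True
    return bool(rng.random() < math.exp(log_p))


# ---------------------------------------------------------------------------
# Move descriptions (consumed by EnergyModel.delta_energy and the ledger)
# ---------------------------------------------------------------------------

@dataclass
class SidechainChange:
    position: tuple
    rotamer: object

    def affected(self, pose):
        return ({tuple(self.position)}, False)

    def apply(self, pose):
        build_sidechain(pose, self.position, self.rotamer)


@dataclass
class BackrubChange:
    move: BackrubMove

    def affected(self, pose):
        keys = {tuple(self.move.pivot)}
        prev_r, next_r = pose.neighbors(tuple(self.move.pivot))
        for r in (prev_r, next_r):
            if r is not None:
                keys.add(r.key)
        return (keys, False)

    def apply(self, pose):
        apply_backrub(pose, self.move)


@dataclass
class LigandChange:
    rotation: np.ndarray
    translation: np.ndarray
    origin: np.ndarray
    conformer: int | None = None

    def affected(self, pose):
        return (set(), True)

    def apply(self, pose):
        pose.ligand.apply_rigid(self.rotation, self.translation, self.origin)
        if self.conformer is not None:
            pose.ligand.active_conformer = self.conformer


# ---------------------------------------------------------------------------
# Pivot-residue interaction energy (fast path used inside the move loop)
# ---------------------------------------------------------------------------

class _PivotScorer:
    """Caches the environment of a pivot so candidate rotamers score quickly.

    The energy it returns is exactly the sum of terms that involve the pivot
    residue: its one-body energy, its two-body terms against every residue
    inside the interaction gate, and its (weighted) ligand terms.  The
    environment (every residue but the pivot, and the ligand) must not move
    while a scorer instance is in use.
    """

    def __init__(self, model: EnergyModel, pose: Pose, pivot):
        self.model = model
        self.pose = pose
        self.pivot = tuple(pivot)
        cfg = model.config
        res = pose.residue(self.pivot)
        self.res = res
        ca = res.backbone["CA"].coords
        prev_r, next_r = pose.neighbors(self.pivot)
        env_xyz, env_el, col_w = [], [], []
        self.env_donors, self.env_acceptors = [], []
        self.adjacent = []  # (residue, is_prev, column slice, donors, acceptors)
        for r2 in pose.residues:
            if r2.key == self.pivot:
                continue
            if np.linalg.norm(r2.backbone["CA"].coords - ca) > cfg.cutoff + 12.0:
                continue
            atoms = r2.atoms
            start = len(env_xyz)
            for a in atoms:
                env_xyz.append(a.coords)
                env_el.append(a.element)
                col_w.append(1.0)
            d, acc = model._donors_acceptors(r2)
            if r2 is prev_r or r2 is next_r:
                self.adjacent.append(
                    {
                        "res": r2,
                        "names": [a.name for a in atoms],
                        "is_prev": r2 is prev_r,
                        "cols": slice(start, len(env_xyz)),
                        "donors": d,
                        "acceptors": acc,
                    }
                )
            else:
                self.env_donors.extend(d)
                self.env_acceptors.extend(acc)
        self.lig_da = None
        if pose.ligand is not None:
            lig = pose.ligand
            for i, xyz in enumerate(lig.coords):
                env_xyz.append(xyz)
                env_el.append(lig.elements[i])
                col_w.append(cfg.w_lig)
            self.lig_da = model._ligand_donors_acceptors(lig)
        self.env_xyz = np.array(env_xyz) if env_xyz else None
        self.env_el = tuple(env_el)
        self.col_w = np.array(col_w)
        self._mask_cache: dict[str, np.ndarray] = {}

    def _mask(self, aa: str, names) -> np.ndarray:
        """Column weights x adjacent-residue bond exclusions, cached per aa."""
        mask = self._mask_cache.get(aa)
        if mask is None:
            mask = np.tile(self.col_w, (len(names), 1))
            for adj in self.adjacent:
                sub = self.model._interresidue_mask(
                    self.res, adj["res"], names, adj["names"]
                )
                mask[:, adj["cols"]] *= sub
            self._mask_cache[aa] = mask
        return mask

    def energy(self, rot_prob: float | None = None) -> float:
        """Interaction energy of the pivot residue in its current state.

        `rot_prob` short-circuits the rotamer self-energy with -ln(prob)
        when the current side chain is a known library rotamer; otherwise
        the nearest-rotamer lookup is used (identical result for library
        rotamers).
        """
        model, pose, res = self.model, self.pose, self.res
        cfg = model.config
        atoms = res.atoms
        xyz = np.array([a.coords for a in atoms])
        names = [a.name for a in atoms]
        e = model.intra_residue_energy(res, xyz, names)
        if rot_prob is not None:
            e += cfg.w_rotamer * -math.log(rot_prob)
        else:
            e += cfg.w_rotamer * model.rotamer_self_energy(pose, self.pivot)
        e += cfg.reference_energies.get(res.aa, 0.0)
        if self.env_xyz is None:
            return e
        el = tuple(a.element for a in atoms)
        vdw, _ = model.lj_matrix(xyz, el, self.env_xyz, self.env_el)
        e += cfg.w_vdw * float((vdw * self._mask(res.aa, names)).sum())
        donors, acceptors = model._donors_acceptors(res)
        e += cfg.w_hbond * (
            model._hbond_energy(donors, self.env_acceptors)
            + model._hbond_energy(self.env_donors, acceptors)
        )
        for adj in self.adjacent:
            r2 = adj["res"]
            if adj["is_prev"]:
                d_c = chem.atom_graph_dist_to(r2.aa, "C")
                d_n = chem.atom_graph_dist_to(res.aa, "N")
                excl_fwd = lambda dn, an: d_n.get(dn, 99) + 1 + d_c.get(an, 99) <= 3
                excl_rev = lambda dn, an: d_c.get(dn, 99) + 1 + d_n.get(an, 99) <= 3
            else:
                d_c = chem.atom_graph_dist_to(res.aa, "C")
                d_n = chem.atom_graph_dist_to(r2.aa, "N")
                excl_fwd = lambda dn, an: d_c.get(dn, 99) + 1 + d_n.get(an, 99) <= 3
                excl_rev = lambda dn, an: d_n.get(dn, 99) + 1 + d_c.get(an, 99) <= 3
            e += cfg.w_hbond * (
                model._hbond_energy(donors, adj["acceptors"], excl_fwd)
                + model._hbond_energy(adj["donors"], acceptors, excl_rev)
            )
        if self.lig_da is not None:
            ldon, lacc = self.lig_da
            e += cfg.w_lig * cfg.w_hbond * (
                model._hbond_energy(donors, lacc) + model._hbond_energy(ldon, acceptors)
            )
        return e


# ---------------------------------------------------------------------------
# Coupled moves
# ---------------------------------------------------------------------------

def coupled_protein_move(
    pose: Pose,
    task: DesignTask,
    rotlib,
    model: EnergyModel,
    config: SamplerConfig,
    rng: np.random.Generator,
):
    """Propose one coupled backbone + side-chain move.

    Returns (proposed_pose, delta_E, pivot, theta).  The input pose is not
    modified.
    """
    positions = sorted(task.design_positions | task.repack_positions)
    if not positions:
        raise ValueError("no design or repack positions")
    pivot = positions[int(rng.integers(len(positions)))]
    work = pose.copy()

    theta = 0.0
    delta_bb = 0.0
    if config.backbone == "flexible":
        prev_r, next_r = work.neighbors(pivot)
        if prev_r is not None and next_r is not None:
            theta = sample_backrub_angle(BackrubParams(config.sigma_theta), rng)
            if abs(theta) < 90.0:
                change = BackrubChange(BackrubMove(pivot, theta))
                footprint, _ = change.affected(work)
                before = model.partial(pose, footprint)
                change.apply(work)
                delta_bb = model.partial(work, footprint) - before
            else:
                theta = 0.0

    res = work.residue(pivot)
    if pivot in task.design_positions:
        allowed = task.aas_for(pivot)
    else:
        allowed = (res.aa,)
    rotset = get_rotamers(work, pivot, allowed, rotlib)

    scorer = _PivotScorer(model, work, pivot)
    e_current = scorer.energy()

    from .rotamers import align_template, apply_chis, sidechain_records

    by_aa = rotset.by_aa()
    aa_list = sorted(by_aa)
    aligned: dict[str, np.ndarray] = {}

    def _install(aa, rot):
        base = aligned.get(aa)
        if base is None:
            base = aligned[aa] = align_template(res, aa)
        res.aa = aa
        res.sidechain = sidechain_records(aa, apply_chis(aa, base, rot.chis))

    if config.sc_selection == "boltzmann":
        winners = {}
        winner_energies = {}
        for aa in aa_list:
            rots = by_aa[aa]
            energies = []
            for r in rots:
                _install(aa, r)
                energies.append(scorer.energy(rot_prob=r.prob) - e_current)
            idx, _ = boltzmann_select(energies, config.kT, rng)
            winners[aa] = rots[idx]
            winner_energies[aa] = energies[idx]
        if len(aa_list) > 1:
            E_aa = [winner_energies[aa] for aa in aa_list]
            aidx, _ = boltzmann_select(E_aa, config.kT, rng)
            chosen_aa = aa_list[aidx]
        else:
            chosen_aa = aa_list[0]
        chosen = winners[chosen_aa]
        delta_sc = winner_energies[chosen_aa]
    else:
        # uniform variant: both stages are uniform draws, so only the energy
        # of the winning candidate is ever needed
        chosen_aa = aa_list[int(rng.integers(len(aa_list)))] if len(aa_list) > 1 else aa_list[0]
        rots = by_aa[chosen_aa]
        chosen = rots[int(rng.integers(len(rots)))]
        _install(chosen_aa, chosen)
        delta_sc = scorer.energy(rot_prob=chosen.prob) - e_current
    _install(chosen_aa, chosen)
    return work, delta_bb + delta_sc, pivot, theta


def coupled_ligand_move(
    pose: Pose,
    model: EnergyModel,
    config: SamplerConfig,
    rng: np.random.Generator,
):
    """Propose one coupled ligand rigid-body + conformer move.

    Rotation: random axis through the ligand heavy-atom centroid, angle
    ~ N(0, sigma_rot^2).  Translation: isotropic with per-axis sd
    sigma_trans / sqrt(3), so the displacement vector itself has the
    configured standard deviation.  Returns (proposed_pose, delta_E).
    """
    if pose.ligand is None:
        raise ValueError("pose has no ligand")
    work = pose.copy()
    lig = work.ligand

    e_before = model.partial(pose, [], include_ligand=True)

    axis = rng.normal(size=3)
    n = np.linalg.norm(axis)
    axis = axis / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])
    angle = rng.normal(0.0, config.sigma_rot) if config.sigma_rot > 0 else 0.0
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(axis * np.deg2rad(angle)).as_matrix()
    per_axis_sd = config.sigma_trans / math.sqrt(3.0)
    t = rng.normal(0.0, per_axis_sd, size=3) if config.sigma_trans > 0 else np.zeros(3)
    lig.apply_rigid(R, t, lig.centroid())

    conformers = ligand_conformer_set(lig)
    if len(conformers) > 1:
        current = lig.active_conformer
        energies = []
        for c in conformers:
            lig.active_conformer = c.index
            energies.append(model.partial(work, [], include_ligand=True))
        lig.active_conformer = current
        rel = [e - energies[current] for e in energies]
        if config.sc_selection == "boltzmann":
            idx, _ = boltzmann_select(rel, config.kT, rng)
        else:
            idx = int(rng.integers(len(conformers)))
        lig.active_conformer = conformers[idx].index
        e_after = energies[idx]
    else:
        e_after = model.partial(work, [], include_ligand=True)
    return work, e_after - e_before


# ---------------------------------------------------------------------------
# Simulation drivers
# ---------------------------------------------------------------------------

def run_coupled_moves(
    pose: Pose,
    task: DesignTask,
    rotlib,
    model: EnergyModel,
    config: SamplerConfig,
) -> DesignTrace:
    """Run one coupled-moves simulation; fixed seed gives a reproducible trace."""
    task.validate(pose)
    rng = np.random.default_rng(config.seed)
    design_keys = tuple(sorted(task.design_positions))
    pose = pose.copy()
    total = model.score(pose).total

    seq = pose.sequence(design_keys)
    trace = DesignTrace(
        design_positions=design_keys,
        sequences=[seq],
        move_ledger=[],
        best_pose_per_sequence={seq: pose.copy()},
        best_energy_per_sequence={seq: total},
    )

    for _ in range(config.n_moves):
        do_ligand = False
        if pose.ligand is not None and config.p_ligand > 0:
            do_ligand = bool(rng.random() < config.p_ligand)
        if do_ligand:
            proposal, dE = coupled_ligand_move(pose, model, config, rng)
            record = MoveRecord("ligand", None, dE, False)
        else:
            proposal, dE, pivot, theta = coupled_protein_move(
                pose, task, rotlib, model, config, rng
            )
            record = MoveRecord("protein", pivot, dE, False, theta)
        if metropolis_accept(dE, config.kT, rng):
            record.accepted = True
            pose = proposal
            total += dE
            seq = pose.sequence(design_keys)
            if seq not in trace.sequences:
                trace.sequences.append(seq)
            best = trace.best_energy_per_sequence.get(seq)
            if best is None or total < best:
                trace.best_energy_per_sequence[seq] = total
                trace.best_pose_per_sequence[seq] = pose.copy()
        trace.move_ledger.append(record)
    return trace


def run_batch(pose, task, rotlib, model, config: SamplerConfig) -> list[DesignTrace]:
    """Run config.n_sims independent simulations; simulation s uses seed base+s."""
    traces = []
    for s in range(config.n_sims):
        cfg = SamplerConfig(**{**config.__dict__, "seed": config.seed + s})
        traces.append(run_coupled_moves(pose, task, rotlib, model, cfg))
    return traces


@dataclass
class AnnealSchedule:
    """Geometric cooling for the baseline packer."""

    kT_start: float = 100.0
    kT_end: float = 0.3
    n_stages: int = 8

    def stage_temperatures(self):
        ratio = (self.kT_end / self.kT_start) ** (1.0 / max(1, self.n_stages - 1))
        return [self.kT_start * ratio**k for k in range(self.n_stages)]


def run_fixed_backbone_design(
    pose: Pose,
    task: DesignTask,
    rotlib,
    model: EnergyModel,
    config: SamplerConfig,
    schedule: AnnealSchedule | None = None,
) -> DesignTrace:
    """Fixed-backbone simulated-annealing packer (the baseline method).

    Uniform random (position, rotamer) proposals over design and repack
    positions; Metropolis acceptance with a geometrically cooled
    temperature; backbone and ligand stay frozen.  The trace has the same
    form as a coupled-moves trace so both methods feed the same analyses.
    """
    task.validate(pose)
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(config.seed)
    design_keys = tuple(sorted(task.design_positions))
    positions = sorted(task.design_positions | task.repack_positions)
    if not positions:
        raise ValueError("no design or repack positions")
    pose = pose.copy()
    total = model.score(pose).total
    seq = pose.sequence(design_keys)
    trace = DesignTrace(
        design_positions=design_keys,
        sequences=[seq],
        move_ledger=[],
        best_pose_per_sequence={seq: pose.copy()},
        best_energy_per_sequence={seq: total},
    )
    temps = schedule.stage_temperatures()
    per_stage = max(1, config.n_moves // len(temps))
    for kT in temps:
        for _ in range(per_stage):
            pivot = positions[int(rng.integers(len(positions)))]
            res = pose.residue(pivot)
            allowed = task.aas_for(pivot) if pivot in task.design_positions else (res.aa,)
            rotset = get_rotamers(pose, pivot, allowed, rotlib)
            rot = rotset.rotamers[int(rng.integers(len(rotset.rotamers)))]
            scorer = _PivotScorer(model, pose, pivot)
            e_cur = scorer.energy()
            saved_sc, saved_aa = list(res.sidechain), res.aa
            build_sidechain(pose, pivot, rot)
            dE = scorer.energy() - e_cur
            accepted = metropolis_accept(dE, kT, rng)
            if accepted:
                total += dE
                seq = pose.sequence(design_keys)
                if seq not in trace.sequences:
                    trace.sequences.append(seq)
                best = trace.best_energy_per_sequence.get(seq)
                if best is None or total < best:
                    trace.best_energy_per_sequence[seq] = total
                    trace.best_pose_per_sequence[seq] = pose.copy()
            else:
                res.sidechain = saved_sc
                res.aa = saved_aa
            trace.move_ledger.append(MoveRecord("protein", pivot, dE, accepted))
    return trace


def pool_sequences(traces) -> SequenceSet:
    """Union of unique sequences across traces, first-occurrence order."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to pool")
    positions = traces[0].design_positions
    for t in traces[1:]:
        if t.design_positions != positions:
            raise ValueError("traces have inconsistent design positions")
    seen = {}
    for t in traces:
        for s in t.sequences:
            if s not in seen:
                seen[s] = None
    return SequenceSet(positions, list(seen))
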