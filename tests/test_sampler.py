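import itertools
import math

import numpy as np
import pytest

from coupledmoves import fixtures
from coupledmoves.energy import EnergyConfig, EnergyModel
from coupledmoves.rotamers import build_sidechain, get_rotamers
from coupledmoves.sampler import (
    DesignTrace,
    MoveRecord,
    SamplerConfig,
    SequenceSet,
    boltzmann_select,
    coupled_ligand_move,
    coupled_protein_move,
    metropolis_accept,
    pool_sequences,
    run_coupled_moves,
    run_fixed_backbone_design,
)
from coupledmoves.structure import DesignTask


@pytest.fixture(scope="module")
def toy_model(rotlib):
    return EnergyModel(EnergyConfig(hbond_depth=4.0), rotlib)


class TestBoltzmannSelect:
    def test_symmetric_energies_give_half_half(self):
        _, p = boltzmann_select([0.0, 0.0], 0.6, np.random.default_rng(0))
        assert np.allclose(p, [0.5, 0.5])

    def test_closed_form_two_thirds(self):
        _, p = boltzmann_select([0.0, 0.6 * math.log(2)], 0.6, np.random.default_rng(0))
        assert np.allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_huge_energy_no_overflow(self):
        _, p = boltzmann_select([0.0, 1e9], 0.6, np.random.default_rng(0))
        assert np.allclose(p, [1.0, 0.0])
        assert abs(p.sum() - 1.0) < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_select([], 0.6, np.random.default_rng(0))

    def test_sampling_matches_probabilities(self):
        rng = np.random.default_rng(7)
        energies = [0.0, 0.3, 1.1]
        _, p = boltzmann_select(energies, 0.6, rng)
        n = 10_000
        counts = np.zeros(3)
        for _ in range(n):
            idx, _ = boltzmann_select(energies, 0.6, rng)
            counts[idx] += 1
        sigma = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) < 3 * sigma + 1).all()


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-5.0, 0.6, rng) for _ in range(100))

    def test_closed_form_half_acceptance(self):
        rng = np.random.default_rng(1)
        dE = 0.6 * math.log(2)
        n = 10_000
        acc = sum(metropolis_accept(dE, 0.6, rng) for _ in range(n))
        sigma = math.sqrt(n * 0.25)
        assert abs(acc - n / 2) < 3 * sigma

    def test_huge_uphill_never_accepted(self):
        rng = np.random.default_rng(2)
        assert not any(metropolis_accept(1e6, 0.6, rng) for _ in range(10_000))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), 0.6, np.random.default_rng(0))


class TestCoupledProtein:
    def test_repack_only_position_keeps_identity(self, spec_pair, rotlib, toy_model):
        native, _, _, _ = spec_pair
        task = DesignTask(repack_positions={("A", 4)})
        cfg = SamplerConfig(seed=3)
        rng = np.random.default_rng(3)
        proposal, dE, pivot, theta = coupled_protein_move(
            native, task, rotlib, toy_model, cfg, rng
        )
        assert proposal.residue(("A", 4)).aa == native.residue(("A", 4)).aa

    def test_clashing_amino_acid_essentially_never_selected(self, spec_pair, rotlib, toy_model):
        """At kT 0.6 a +50-unit clash has Boltzmann weight < 1e-10."""
        _, nonnative, task, notes = spec_pair
        # M clashes with the probe (notes show it far above everything else)
        assert notes["M"] > notes["S"] + 20
        cfg = SamplerConfig(seed=0, backbone="fixed")
        rng = np.random.default_rng(0)
        picks = []
        for _ in range(300):
            proposal, _, _, _ = coupled_protein_move(
                nonnative, task, rotlib, toy_model, cfg, rng
            )
            picks.append(proposal.residue(("A", 4)).aa)
        assert "M" not in picks

    def test_fixed_backbone_selection_matches_analytic(self, rotlib):
        """Two-candidate toy: selection frequencies follow the Boltzmann law."""
        pose = fixtures.make_helix("AAAAA", rotlib=rotlib)
        model = EnergyModel(EnergyConfig(), rotlib)
        task = DesignTask(design_positions={("A", 3)}, allowed_aas={("A", 3): ("A", "G")})
        cfg = SamplerConfig(seed=0, backbone="fixed", p_ligand=0.0)
        rng = np.random.default_rng(11)
        # analytic: per-aa winner energies are deterministic on a fixed backbone
        sets = get_rotamers(pose, ("A", 3), ("A", "G"), rotlib)
        from coupledmoves.sampler import _PivotScorer

        work = pose.copy()
        scorer = _PivotScorer(model, work, ("A", 3))
        e_cur = scorer.energy()
        best = {}
        res = work.residue(("A", 3))
        for aa, rots in sets.by_aa().items():
            energies = []
            for r in rots:
                build_sidechain(work, ("A", 3), r)
                energies.append(scorer.energy(rot_prob=r.prob) - e_cur)
            best[aa] = min(energies)  # single-rotamer groups here
        dE = best["G"] - best["A"]
        p_G = math.exp(-dE / 0.6) / (1 + math.exp(-dE / 0.6))
        n = 10_000
        count_G = 0
        for _ in range(n):
            proposal, _, _, _ = coupled_protein_move(pose, task, rotlib, model, cfg, rng)
            count_G += proposal.residue(("A", 3)).aa == "G"
        sigma = math.sqrt(n * p_G * (1 - p_G))
        assert abs(count_G - n * p_G) < 3 * sigma


class TestCoupledLigand:
    def test_zero_widths_single_conformer_identity(self, spec_pair, toy_model):
        native, _, _, _ = spec_pair
        cfg = SamplerConfig(sigma_rot=0.0, sigma_trans=0.0, seed=0)
        rng = np.random.default_rng(0)
        proposal, dE = coupled_ligand_move(native, toy_model, cfg, rng)
        assert np.allclose(proposal.ligand.coords, native.ligand.coords)
        assert abs(dE) < 1e-9

    def test_translation_sd_matches_configuration(self):
        """The displacement vector has sd sigma_trans (per-axis sigma/sqrt(3))."""
        rng = np.random.default_rng(5)
        n = 100_000
        draws = rng.normal(0.0, 0.1 / math.sqrt(3), size=(n, 3))
        per_axis = draws.std(axis=0)
        assert np.all(np.abs(per_axis - 0.1 / math.sqrt(3)) / (0.1 / math.sqrt(3)) < 0.02)

    def test_high_energy_conformer_rarely_chosen(self, spec_pair, toy_model, rotlib):
        native, _, _, _ = spec_pair
        pose = native.copy()
        # second conformer translated into the pocket residue -> large penalty
        lig = pose.ligand
        toward = pose.residue(("A", 4)).backbone["CA"].coords - lig.coords[0]
        lig.conformers.append(lig.conformers[0] + toward * 0.8)
        cfg = SamplerConfig(sigma_rot=0.0, sigma_trans=0.0, seed=0)
        rng = np.random.default_rng(9)
        chosen = [
            coupled_ligand_move(pose, toy_model, cfg, rng)[0].ligand.active_conformer
            for _ in range(200)
        ]
        assert chosen.count(1) == 0

    def test_missing_ligand_rejected(self, helix, toy_model):
        with pytest.raises(ValueError):
            coupled_ligand_move(helix, toy_model, SamplerConfig(), np.random.default_rng(0))


class TestRunCoupledMoves:
    def test_no_design_positions_single_sequence(self, spec_pair, rotlib, toy_model):
        native, _, _, _ = spec_pair
        task = DesignTask(repack_positions={("A", 4)})
        cfg = SamplerConfig(n_moves=50, seed=1)
        trace = run_coupled_moves(native, task, rotlib, toy_model, cfg)
        assert trace.sequences == [""]
        assert 0.0 <= trace.acceptance_ratio <= 1.0

    def test_fixed_seed_bit_reproducible(self, spec_pair, rotlib, toy_model):
        native, _, task, _ = spec_pair
        cfg = SamplerConfig(n_moves=60, seed=5)
        a = run_coupled_moves(native, task, rotlib, toy_model, cfg)
        b = run_coupled_moves(native, task, rotlib, toy_model, cfg)
        assert a.sequences == b.sequences
        assert [(m.move_type, m.position, m.delta_E, m.accepted, m.theta)
                for m in a.move_ledger] == [
            (m.move_type, m.position, m.delta_E, m.accepted, m.theta)
            for m in b.move_ledger
        ]

    def test_forced_mutation_enriched(self, spec_pair, rotlib, toy_model):
        """The probe-complement serine takes over under the non-native ligand."""
        _, nonnative, task, _ = spec_pair
        hits = 0
        for seed in range(5):
            cfg = SamplerConfig(n_moves=150, seed=seed)
            trace = run_coupled_moves(nonnative, task, rotlib, toy_model, cfg)
            best_seq = min(trace.best_energy_per_sequence, key=trace.best_energy_per_sequence.get)
            hits += best_seq[0] == "S"  # pocket position of the (pocket, bystander) pair
        assert hits >= 4

    def test_ligand_free_pose_independent_of_p_ligand(self, rotlib):
        pose = fixtures.make_helix("AALSFAA", rotlib=rotlib)
        model = EnergyModel(EnergyConfig(), rotlib)
        task = DesignTask(design_positions={("A", 4)}, allowed_aas={("A", 4): ("A", "S", "V")})
        a = run_coupled_moves(pose, task, rotlib, model, SamplerConfig(n_moves=40, seed=2, p_ligand=0.0))
        b = run_coupled_moves(pose, task, rotlib, model, SamplerConfig(n_moves=40, seed=2, p_ligand=0.5))
        assert a.sequences == b.sequences
        assert [m.delta_E for m in a.move_ledger] == [m.delta_E for m in b.move_ledger]


class TestFixedBackboneDesign:
    def test_backbone_and_ligand_frozen(self, spec_pair, rotlib, toy_model):
        native, _, task, _ = spec_pair
        cfg = SamplerConfig(n_moves=80, seed=4, backbone="fixed")
        trace = run_fixed_backbone_design(native, task, rotlib, toy_model, cfg)
        final = trace.best_pose_per_sequence[trace.sequences[0]]
        for key in [r.key for r in native.residues]:
            for nm, atom in native.residue(key).backbone.items():
                assert np.array_equal(atom.coords, final.residue(key).backbone[nm].coords)
        assert np.allclose(final.ligand.coords, native.ligand.coords)

    def test_recovers_global_minimum(self, spec_pair, rotlib, toy_model):
        """Annealing reaches the brute-force optimum on a small design problem."""
        _, nonnative, _, _ = spec_pair
        allowed = {("A", 2): ("A", "V"), ("A", 4): ("A", "S"), ("A", 6): ("A", "G")}
        task = DesignTask(design_positions=set(allowed), allowed_aas=allowed)
        keys = sorted(allowed)
        rotsets = {k: get_rotamers(nonnative, k, allowed[k], rotlib).rotamers for k in keys}
        best_seq, best_e = None, None
        for combo in itertools.product(*[rotsets[k] for k in keys]):
            w = nonnative.copy()
            for k, r in zip(keys, combo):
                build_sidechain(w, k, r)
            e = toy_model.score(w).total
            if best_e is None or e < best_e:
                best_e, best_seq = e, w.sequence(keys)
        hits = 0
        for seed in range(5):
            cfg = SamplerConfig(n_moves=400, seed=seed, backbone="fixed")
            tr = run_fixed_backbone_design(nonnative, task, rotlib, toy_model, cfg)
            found = min(tr.best_energy_per_sequence, key=tr.best_energy_per_sequence.get)
            hits += found == best_seq
        assert hits >= 4

    def test_zero_temperature_greedy_on_one_position(self, spec_pair, rotlib, toy_model):
        from coupledmoves.sampler import AnnealSchedule

        _, nonnative, _, _ = spec_pair
        task = DesignTask(design_positions={("A", 4)}, allowed_aas={("A", 4): ("A", "S")})
        sched = AnnealSchedule(kT_start=1e-6, kT_end=1e-6, n_stages=1)
        cfg = SamplerConfig(n_moves=200, seed=0, backbone="fixed")
        tr = run_fixed_backbone_design(nonnative, task, rotlib, toy_model, cfg, sched)
        best = min(tr.best_energy_per_sequence, key=tr.best_energy_per_sequence.get)
        assert best == "S"  # the hydrogen-bonded serine is the greedy minimum


class TestPoolSequences:
    def _trace(self, seqs, positions=(("A", 4),)):
        return DesignTrace(tuple(positions), list(seqs), [], {}, {})

    def test_union_without_duplicates(self):
        pooled = pool_sequences([self._trace(["L", "S"]), self._trace(["S", "A"])])
        assert pooled.sequences == ["L", "S", "A"]

    def test_single_trace_identity(self):
        pooled = pool_sequences([self._trace(["L", "V", "S"])])
        assert pooled.sequences == ["L", "V", "S"]

    def test_matches_set_oracle_over_many_traces(self):
        rng = np.random.default_rng(0)
        traces = []
        for _ in range(20):
            seqs = ["".join(rng.choice(list("ALSV"), 2)) for _ in range(6)]
            traces.append(self._trace(list(dict.fromkeys(seqs)), (("A", 1), ("A", 2))))
        pooled = pool_sequences(traces)
        brute = list(dict.fromkeys(s for t in traces for s in t.sequences))
        assert pooled.sequences == brute

    def test_inconsistent_positions_rejected(self):
        with pytest.raises(ValueError):
            pool_sequences([self._trace(["L"]), self._trace(["L"], positions=(("A", 5),))])

    def test_fasta_round_trip(self, tmp_path):
        pooled = SequenceSet((("A", 4),), ["L", "S", "A"])
        path = tmp_path / "pooled.fasta"
        pooled.write_fasta(path)
        back = SequenceSet.read_fasta(path)
        assert back.sequences == pooled.sequences
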