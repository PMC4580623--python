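# coupledmoves

Flexible-backbone design of protein–ligand interfaces by **coupled moves**:
Monte Carlo sampling in which every proposal combines a local backbone
perturbation (a backrub move) or a ligand rigid-body perturbation with a
simultaneously chosen side-chain rotamer / amino-acid identity (or ligand
conformer), accepted or rejected as a single unit.

The package is for structural-bioinformatics work on enzyme specificity
re-design and binding-site sequence-tolerance prediction: given a
protein–ligand complex it samples the set of sequences a binding site
tolerates, and given two such sets (for a native and a non-native ligand)
it ranks candidate specificity-switching mutations.

## The method

A protein move at pivot residue *i*:

1. **Backrub**: rotate the segment between Cα(i−1) and Cα(i+1) about the
   axis through them by θ ~ N(0, σ²), σ = 4.57° (the spread of backbone
   rotations observed between alternate conformations in high-resolution
   crystal structures), then counter-rotate the flanking peptide planes to
   minimize C–O and N–H displacement. Pivot Cα atoms are exact fixed
   points; bond lengths are rigorously preserved.
2. **Boltzmann-coupled side-chain choice**: on the new backbone, for each
   allowed amino acid select a rotamer with probability
   P(E_r) = e^(−E_r/kT) / Σ_s e^(−E_s/kT) (E_r relative to the current side
   chain), then select an amino acid among the per-amino-acid winners the
   same way. kT = 0.6.
3. **Metropolis**: accept the coupled proposal with
   min(1, e^(−ΔE/kT)) at the same kT.

Ligand moves substitute a rigid-body perturbation (1° rotation sd, 0.1 Å
translation sd) plus Boltzmann conformer selection; a move is a ligand move
with probability 0.1. Defaults are 1,000 moves per simulation and 20
pooled, redundancy-filtered simulations.

Evaluation follows two procedures. **Percent enrichment**:
PE(WT→MUT) = %non-native − %native over the pooled unique sequences, with
descending-PE rank and percentile; a positive PE marks a predicted
specificity switch. **Profile similarity**: per binding-site position,
1 − D_JS(p, q) between designed and natural amino-acid distributions
(equal-weight Jensen–Shannon divergence, base-2 logs), alongside sequence
entropy H = −Σ P_x log₂₀ P_x, entropy tertiles, a uniform null model,
Fisher exact and paired t significance tests.

The energy function is pluggable (one-body/two-body decomposition with
exact incremental rescoring and a protein–ligand weight `w_lig`); the
shipped reference score is a simple heavy-atom model — soft Lennard-Jones
with a linearized repulsive core, a directional donor–acceptor
hydrogen-bond term, rotamer self-energies −ln p, and per-amino-acid
reference energies. A compact backbone-dependent rotamer library is
packaged; larger tables in the same TSV format drop in. Everything is
verified on self-validating synthetic systems (ideal helices with probe
ligands whose design ground truth is established by brute-force
enumeration at build time) — see `docs/methods.md`.

## Worked example: recovering a specificity-switching mutation

The packaged toy system is a seven-residue helix with an aspartate pocket.
The native ligand is a donor probe hydrogen-bonded to the aspartate
carboxylate; the non-native ligand is an acceptor probe that only a serine
hydroxyl can reach, so the ground-truth switch is D→S:

```python
from coupledmoves import fixtures, metrics
from coupledmoves.energy import EnergyConfig, EnergyModel
from coupledmoves.rotamers import RotamerLibrary
from coupledmoves.sampler import SamplerConfig, pool_sequences, run_coupled_moves

rotlib = RotamerLibrary.packaged()
native, nonnative, task, notes = fixtures.specificity_pair(seed=0, rotlib=rotlib)
model = EnergyModel(EnergyConfig(hbond_depth=4.0), rotlib)

pooled = {}
for name, pose in [("native", native), ("nonnative", nonnative)]:
    runs = [run_coupled_moves(pose, task, rotlib, model,
                              SamplerConfig(n_moves=250, seed=s))
            for s in range(10)]
    pooled[name] = pool_sequences(runs)

rows = metrics.enrichment_analysis(
    pooled["native"].sequences, pooled["nonnative"].sequences,
    direction="wt2mut", reference_seq="DA",
)
for r in rows[:3]:
    print(f"pos {r.position}  {r.from_aa}->{r.to_aa}  "
          f"%nat={r.pct_native:.1f}  %non={r.pct_nonnative:.1f}  "
          f"PE={r.PE:+.1f}  rank={r.rank}")
```

Output:

```
pos 0  D->S  %nat=0.0  %non=44.4  PE=+44.4  rank=1
pos 1  A->S  %nat=22.2  %non=38.9  PE=+16.7  rank=2
pos 0  D->A  %nat=0.0  %non=5.6  PE=+5.6  rank=3
```

Position 0 is the pocket; the ground-truth D→S mutation is heavily enriched
in the sequences designed for the non-native ligand (PE ≈ +46, rank 1),
while the bystander position (1) shows only drift-level enrichment. The
same analysis is available from the shell:

```bash
coupledmoves fixtures make-toy --out toy/      # PDB + SDF + task + notes
coupledmoves design --pdb toy/complex.pdb --ligand-code LIG \
    --task toy/task.txt --n-moves 250 --n-sims 10 --seed 0 \
    --out-prefix run_native/
# ... repeat with the swapped-ligand complex, then:
coupledmoves enrich --native run_native/pooled.fasta \
    --nonnative run_nonnative/pooled.fasta --direction wt2mut
```

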