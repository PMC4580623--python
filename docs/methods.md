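# Methods

## The coupled-moves protocol

`coupledmoves` implements flexible-backbone design of protein–ligand
interfaces by Monte Carlo sampling in which every proposal couples a
backbone (or ligand rigid-body) perturbation to a simultaneous,
energy-biased choice of side-chain rotamer and amino-acid identity, accepted
or rejected as one unit.

A single protein move:

1. Pick a pivot residue *i* uniformly from the design ∪ repack positions.
2. Apply a three-residue backrub: rotate C,O of *i−1*, all atoms of *i*, and
   N(,H) of *i+1* about the Cα(i−1)→Cα(i+1) axis by θ ~ N(0, σ²_θ), σ_θ =
   4.57° by default (the standard deviation of backbone rotations observed
   between alternate conformations in high-resolution crystal structures).
   The two flanking peptide planes are then counter-rotated about their own
   Cα–Cα axes by the closed-form angles that minimize the summed squared
   displacement of the C–O and N–H groups from their pre-move positions
   (for a rotation about a fixed axis the objective is
   `const − 2(A cos α + B sin α)`, minimized at `α = atan2(B, A)`).
   Pivot-flanking Cα atoms are exact fixed points and all bond lengths are
   preserved to machine precision; only dihedral degrees of freedom change.
3. On the new backbone, enumerate candidate rotamers at *i* for every
   allowed amino acid (plus the current conformation, so the null move
   always exists). For each amino acid one rotamer is selected with
   probability `P(E_r) ∝ exp(−E_r/kT)` where `E_r` is the energy of rotamer
   *r* relative to the current side chain; an amino acid is then selected
   the same way from the per-amino-acid winners. `kT = 0.6` throughout.
4. Accept or reject the whole coupled move by the Metropolis criterion at
   the same temperature.

A ligand move substitutes a rigid-body perturbation for the backrub:
rotation about a random axis through the heavy-atom centroid with a 1° sd,
translation with a 0.1 Å sd on the displacement vector (per-axis sd
0.1/√3 Å — the alternative reading, 0.1 Å per axis, would give a √3-larger
step), followed by Boltzmann selection of a ligand conformer from the
discrete conformer set (uniform prior). Each move is a ligand move with
probability 0.1 when a ligand is present.

Defaults follow the protocol's published conditions: 1,000 moves per
simulation, 20 independent simulations (simulation *s* seeded `base+s`),
90/10 protein/ligand move mix. Every accepted sequence over the design
positions is recorded once; the lowest-energy pose per unique sequence is
retained; per-simulation FASTA files are pooled with redundancy filtering.

**Variants.** `sc_selection="uniform"` (Uni SC) replaces both selection
stages with uniform draws — only the winning candidate's energy is then
evaluated, since the draws need none. `backbone="fixed"` (Fix BB) skips the
backrub. The fixed-backbone *baseline* is a separate simulated-annealing
packer: uniform (position, rotamer) proposals, geometric cooling over 8
stages from kT 100 to 0.3, backbone and ligand frozen. Its deliverable is
the lowest-energy sequence encountered in the trace; the end-of-annealing
state at kT 0.3 can still hop between near-degenerate sequences.

**A note on the sampler's stationary law.** Boltzmann selection over the
full candidate list is an independence sampler from the target
distribution; composing it with the *plain* Metropolis test double-counts
the energy bias, so on a discrete landscape the chain concentrates as
`exp(−2E/kT)` rather than `exp(−E/kT)` (for two states at energies 0 and
0.6·ln 3 the plain-Metropolis occupancy is [0.9, 0.1]). The protocol uses
plain Metropolis deliberately — it is a sequence-design heuristic, not an
equilibrium estimator. For stationarity verification the discrete-landscape
chain applies the Metropolis–Hastings proposal correction
(`metropolis_accept(..., log_hastings=ΔE/kT)`), under which acceptance is
identically 1 and occupancy matches the Boltzmann closed form [0.75, 0.25]
exactly. Both laws are asserted in the test suite.

## Energy function

The sampler is energy-function agnostic: it needs a one-body/two-body
decomposition, residue–ligand pair terms scalable by `w_lig`, and exact
incremental rescoring (`delta_energy` equals the full-rescore difference).
The reference implementation is a deliberately simple all-heavy-atom score:

- **van der Waals**: `ε[(σ/r)¹² − 2(σ/r)⁶]` with σ the sum of per-element
  radii (C 1.75, N 1.55, O 1.50, S 1.80 Å) and ε the geometric mean of
  per-element well depths (0.12–0.20). The repulsive branch is linearized
  below 0.6 σ so overlapping atoms stay finite. The part of the well above
  its −ε floor inside σ is the *repulsive component*; it alone defines the
  "clash" energy (> 5 units) used to pick repack neighbors, being the only
  term that grows without bound on overlap.
- **hydrogen bonds**: donor/acceptor heavy-atom pairs (backbone N donates,
  backbone O accepts, plus the standard side-chain donors and acceptors),
  distance window 1.5–3.3 Å with optimum 2.8 Å (inverted-parabola radial
  factor), cos² angular falloff about an ideal base–donor–acceptor angle of
  109.5°, well depth 2.0 by default. The chemistry is directional:
  side-chain hydroxyls (Ser/Thr/Tyr) are donors only and ligand atoms
  follow their element (O accepts, N donates through its bonded base atom) —
  with heavy-atom geometry a single oxygen cannot present both roles
  without double counting. No explicit hydrogens are modeled anywhere;
  backbone H atoms present in an input are carried through backrub moves
  unchanged.
- **rotamer self-energy**: −ln p of the nearest library rotamer to the
  current chi angles (zero for Gly/Ala/Pro).
- **reference energies**: 20 per-amino-acid constants, default 0.
- Pairs within three covalent bonds are excluded (intra-residue via the
  template bond graph; across the peptide bond via per-residue distances to
  the C/N anchor atoms). Interaction cutoff 10 Å; residue pairs are gated
  at CA–CA distance cutoff + 12 Å. Protein–ligand terms are multiplied by
  `w_lig` (1.0 default; 2.0/3.0 are the published up-weighting settings).

Solvation and electrostatics are not modeled; `EnergyConfig.extra_term`
accepts a user-supplied callable added to the total. Ligand internal strain
is not scored: conformers enter with a uniform prior and interact with the
protein only.

## Structural model

Residues are heavy-atom records grouped into backbone (N, CA, C, O) and
side chain; chi angles are always recomputed from coordinates. Side chains
are rebuilt from idealized residue templates (the chemical component
dictionary shipped with biotite): the template backbone is superposed onto
the residue's N/CA/C, then each chi bond is rotated to the exact target
dihedral. Proline is a rigid ring with zero sampled chi angles — rotating
its dihedrals independently would break ring closure — and is always placed
whole from the template. Glycine has no side-chain heavy atom; for
distance-shell selection its CA serves as the side-chain surrogate so small
positions remain designable.

The packaged rotamer library is a compact, backbone-dependent table: chi
means and probabilities at two (φ, ψ) bins (helix −60/−50, strand
−120/130) on the 10° grid, written for this package in a documented TSV
format (`AA PHI_BIN PSI_BIN PROB CHI1..CHI4`). Queries snap to the grid and
use the nearest populated bin, which also covers chain termini. A larger
backbone-dependent table in the same format can be dropped in without code
changes. The current side-chain conformation is always appended to every
candidate set with the probability of its nearest same-amino-acid library
rotamer; as a consequence a wild-type identity outside `allowed_aas`
remains reachable as the null move.

## Evaluation metrics

- **Percent enrichment** (specificity benchmark): for a mutation observed
  at a design position, PE(WT→MUT) = %non-native − %native, where the
  percentages are occurrence over the redundancy-filtered pooled unique
  sequences of each condition. PE(MUT→WT) flips the sign. A prediction is
  correct iff PE > 0. Candidates pooled across positions are ranked by
  descending PE (ties broken by position then amino acid, an arbitrary but
  deterministic rule) and percentile = 100·(N − rank + 1)/N, anchoring
  rank 1 at the 100th percentile.
- **Profile similarity** (sequence-tolerance benchmark): per alignment
  column, 1 − D_JS(p, q) with equal mixture weights and base-2 logarithms,
  so the similarity spans [0, 1]. Columns containing gaps are dropped with
  a warning. Sequence entropy uses log base 20 (uniform over the 20 amino
  acids → 1); positions are split into entropy tertiles with any remainder
  assigned to the lower groups. A uniform-distribution null similarity is
  provided for comparison.
- **Significance**: two-sided Fisher's exact test on correct/incorrect
  count tables; paired two-tailed t-test on per-position similarity
  vectors (a paired design has a single difference variance, so the
  "unequal variance" qualifier of the classic description is moot;
  zero-variance differences return p = 1 with a warning).
- **Diagnostics**: glycine fraction over design-position residues of the
  unique sequence set, and the acceptance ratio of all moves.

## Synthetic test systems

The package verifies itself on constructed systems with enumerable ground
truth; no external data is needed.

- **Ideal helices** built by natural-extension-of-reference-frame chaining
  (φ = −57°, ψ = −47°, ω = 180°, standard bond lengths/angles), side chains
  from the library's top rotamers. Idealized geometry keeps the geometric
  invariants exact to tight tolerances.
- **Specificity toy**: a 7-residue helix with an aspartate pocket and a
  hydrogen-bond swap between conditions. The native ligand is a two-atom
  N–C donor probe placed at ideal geometry (2.8 Å, 109.5°) for the top
  aspartate rotamer's carboxylate; the non-native ligand is a single-atom
  acceptor probe at ideal geometry for the top serine rotamer's hydroxyl,
  so each condition has its own hydrogen-bonded optimum and the
  ground-truth switch is D→S. The fixture's energy config deepens the
  hydrogen-bond well to 4.0 so the non-native serine advantage exceeds
  5 kT, and the candidate alphabet excludes the other donor-capable
  residues that could reach the acceptor probe (T, K, R, W, Y, H, N, Q).
  The builder proves the ground truth by brute-force enumeration at
  construction — non-native: gap ≥ 3.0 to wild type and ≥ 1.2 to the
  runner-up; native: serine at least 1.0 above the optimum — and fails
  loudly otherwise. The design task carries a second, ligand-inert
  "bystander" position (verified inert by enumeration): percent occurrence
  is defined over unique sequences, and with a single design position that
  statistic degenerates to 100/|set|; the freely drifting bystander
  restores residence weighting through sequence diversity, as the
  multi-position design regions of real binding sites do. A
  `pocket_mutation_target=None` spec instead requires the ligand's
  contribution to every candidate to be ≤ 0.1 (no-signal control).
- **Crowded pocket** (variant ablation): an 11-residue helix with leucines
  at the same-face positions 5 and 9 packing a two-atom dumbbell at snug
  van-der-Waals contact; both positions design over an 8-letter
  hydrophobic-pocket alphabet. Build-time checks assert a clash-free start
  and a ≥ 1.5-unit glycine penalty at both positions, so glycine
  enrichment can only arise from the sampling dynamics, not the start
  energetics.
- **Discrete landscapes** and **profile-sampled alignments** provide exact
  oracles for the sampling laws and the profile metrics.

What these fixtures do *not* emulate: real rotamer diversity (the compact
library carries a handful of rotamers per amino acid), crystallographic
noise and disorder, solvation, large ligands with many internal degrees of
freedom, and the scale of real binding sites (10–30 designable positions).
Passing tests therefore demonstrate correctness of the algorithms and the
direction of the published effects at desk scale, not quantitative
reproduction of benchmark accuracies obtained with a full molecular-
mechanics energy function on curated structural data.

## Problem sizes and numerical choices

The verification suite runs the full protocol at desk scale: 250-move
simulations for the specificity toy (20 replicate native/non-native pairs)
and 500-move simulations for the 20-seed variant ablation; the annealing
packer uses 400 proposals over 8 cooling stages against a 75-combination
brute-force enumeration. Boltzmann probabilities are computed with a
max-shift so arbitrarily large energies underflow to probability zero
rather than overflow. Ties in enrichment ranking and entropy tertiles are
broken deterministically. Every simulation consumes a single seeded
generator, making traces bit-reproducible; batch runs seed simulation *s*
with `base+s`.

## Known limitations

- The reference score is not a calibrated force field; absolute energies
  and the 5-unit clash threshold are meaningful only within this model.
- Backrub segments are fixed at three residues; no kinematic-closure or
  larger backbone moves, no insertions/deletions.
- The compact rotamer library's two backbone bins make the
  backbone-dependence coarse; sheet/loop conformations share one bin.
- Ligand conformers must be supplied (SDF); no on-the-fly generation.
- Plain-Metropolis acceptance over Boltzmann proposals over-weights
  low-energy states (see above); sequence outputs are enrichment
  rankings, not equilibrium ensembles.
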