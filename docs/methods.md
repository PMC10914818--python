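# Methods

## The optimization model

`leadopt` frames lead optimization as a finite-horizon Markov decision
process over molecular graphs. A state is a pair (molecule, steps
remaining); an episode starts from the lead structure —
3,6-bis(benzimidazol-1-yl)pyridazine, 24 heavy atoms, fully aromatic — and
applies at most `step_limit` graph edits (default 16). The action set of a
state is the union of four families:

1. **atom addition** — attach a new C, N or O by a bond of order *b* to any
   atom with free valence ≥ *b*;
2. **bond addition** — a new bond of any permitted order between an
   unbonded atom pair (ring formation), or a +1 order increment on an
   existing non-aromatic bond;
3. **bond removal** — decrement an existing non-aromatic bond by one order,
   or delete it outright;
4. **no modification** — the unchanged molecule, always legal.

Candidates are sanitized, deduplicated by canonical SMILES (symmetric edits
collapse to one action) and sorted by it, giving a deterministic action
ordering. Free valence is the element's permitted valence (C 4, N 3, O 2;
no formal charges in generated molecules) minus the heavy-atom bond-order
sum, aromatic bonds counting 1.5. Aromatic bonds are frozen — never
incremented or removed — which avoids kekulization churn and preserves the
perceived aromatic systems; aromatic CH carbons keep one open slot, so
substitution on the lead's rings remains available (the chemistry the
optimizer is expected to explore: hydroxyl, imine and amine decorations).
A bond deletion that disconnects the graph keeps the largest fragment
(ties broken by canonical SMILES), so a state is always one connected
molecule. Order increments are +1 only — a single bond cannot jump to a
triple in one action — and triple bonds are restricted to C/N pairs, a
direct consequence of the valence table.

## Rewards

Each episode is scored **terminal-only** on its final molecule by three
evaluators:

- **QED** (drug-likeness, in [0,1]): the standard geometric mean of eight
  desirability-transformed descriptors, delegated to RDKit. The lead scores
  0.502.
- **SA** (synthetic accessibility, in [0,1], 1 = easiest): the
  fragment-contribution score of Ertl & Schuffenhauer (RDKit contrib) on
  its native 1–10 scale, rescaled by (10 − raw)/9. The rescaling is a
  package choice, made because screening treats "easy to synthesize" as
  high; the lead's raw 2.32 maps to 0.853.
- **binding affinity** (kcal/mol, more negative = stronger): either an
  external docking engine behind an adapter, or the deterministic surrogate
  oracle below.

For Q-learning the triple is scalarized as
`w_aff·(−affinity/10) + w_qed·QED + w_sa·SA` with default weights (1,1,1);
the division by 10 puts typical docking energies on roughly the same
[0, 1.4] footing as the two unit-interval scores. All three components are
always logged per episode, so any other weighting can be applied post hoc.

### The surrogate affinity oracle

Docking engines are slow, stochastic, and external. For testing and
desk-scale runs the package ships a deterministic additive surrogate:

    affinity = Σ_atoms contrib(element) + bonus · (#HB donors + #HB acceptors)
               + penalty · max(0, heavy atoms − pivot),   clipped to [−14, 0]

with contrib C = −0.15, N = −0.35, O = −0.40 kcal/mol, bonus = −0.55,
pivot = 26, penalty = +0.35. These values were fixed once so that the lead
(18 C, 6 N, 6 acceptors) scores −8.1 kcal/mol — the same magnitude as the
modal affinity of a production docking-scored run — and so that the oracle
has a learnable gradient: adding hydrogen-bond-capable groups strictly
improves the score, which greedy search can discover in one step. The
surrogate captures none of the geometry of real binding (no pocket, no
poses, no sterics); passing tests against it demonstrate that the learning
loop optimizes what it is given, not that any particular molecule binds
the estrogen receptor.

## The Q-learning agent

Q(s, a) is evaluated on the *resulting* molecule of an action plus the
normalized steps-remaining counter, so one forward pass scores a whole
candidate set. Features are Morgan circular fingerprints (radius 2,
2048 bits by default) with steps-remaining appended. The value network is
a two-hidden-layer ReLU MLP — (1024, 512) by default — trained by Adam
(1e-4) on the one-step TD objective with experience replay (capacity 5000,
batch 128) and a target network synced every 20 episodes; discount
γ = 0.9. The network, Adam, and replay are implemented directly in numpy:
at these sizes a tensor framework buys nothing on one CPU, and the
implementation is ~100 lines that the test suite pins down (fixed points
at γ = 0, finite-loss contracts, reproducibility).

Exploration is linearly decaying ε-greedy: ε starts at 1.0 (pure random
search) and drops by 1/6000 per episode over the default 6000 episodes.
The schedule is held as exact rationals internally, so ε at episodes
{0, 1500, 3000, 4500, 6000} is {1.0, 0.75, 0.5, 0.25, 0.0} bit-exactly.
Greedy ties break toward the lexicographically smallest canonical SMILES.
One master seed fans out (via `numpy.random.SeedSequence`) to network
initialization, action selection and replay sampling; with the surrogate
reward, two runs from the same seed produce byte-identical episode logs.

Episodes whose reward evaluation raises are recorded as failed and the run
continues; if more than 10% of episodes fail, the run aborts.

## Screening

The screen over an episode log keeps records with SA ≥ 0.6, QED ≥ 0.7 and
affinity ≤ −10.0 kcal/mol (defaults; all inclusive, since a candidate
reported with QED exactly 0.70 is treated as passing), deduplicated by
canonical SMILES keeping the best scalar reward. Accompanying statistics:
per-threshold fraction-better values (computed both inclusive and strict,
since the convention is ambiguous in general), Gaussian-KDE densities with
Silverman bandwidth (renormalized on a 512-point grid to integrate to 1
within 1e-6; all-equal input degenerates to a reported point mass), and
Spearman rank correlations of each reward field against episode index
(constant fields are flagged undefined rather than propagating NaN
silently).

## Docking validation

The post-screening stage reproduces an engine workflow without bundling an
engine: a validated grid box (production values 80×60×60 points at
0.375 Å spacing centered on (23.895, 49.094, 134.275) in the receptor
frame, emitted verbatim as `npts`/`spacing`/`gridcenter` fields), receptor
preparation (waters stripped, hydrogens dropped, residue numbering
preserved, nonstandard residues passed through with an explicit warning),
ligand PDBQT writing, and pose handling (default 20 poses, energy-sorted
with stable report order on ties). Both QuickVina-2-style result tables
and AutoDock DLG pose blocks are parsed. The affinity oracle caches by
canonical SMILES and takes the best (minimum) pose energy.

Hydrogen bonds use a heavy-atom geometric criterion: donor–acceptor
distance ≤ 3.5 Å, with the donor–H–acceptor angle ≥ 120° additionally
required when an explicit hydrogen is present; distances class as strong
(≤ 2.5 Å), moderate (≤ 3.5 Å) or weak (beyond, reported only if the cutoff
is raised). Receptor donors/acceptors come from a per-residue table
(backbone N/O plus polar side-chain atoms); ligand donors are N/O bearing
hydrogens, acceptors any N/O. Residues are reported as NAME-number
(e.g. ASN-519). The optimized compounds are treated as free organic
ligands throughout; coordinating them to a metal center before docking
would require engine-specific metal parameters that no general setting
supplies, so metal coordination is deliberately out of scope.

## Synthetic stand-ins and what they do not show

The fixtures module supplies every external input: the lead SMILES; a
synthetic three-residue "toy receptor" (ARG-515, ASN-519, LYS-520 with
idealized side-chain geometry, built programmatically, not taken from any
deposited structure) whose ASN-519 carbonyl oxygen anchors a constructed
hydroxyl probe at an exact chosen distance; mock engine reports in both
result dialects; and a seeded smoke configuration. The toy receptor
exercises parsing, preparation, residue bookkeeping and contact geometry —
it says nothing about real binding pockets. Mock reports exercise the
parse-and-minimize path — they say nothing about an engine's search.

## Problem sizes

The smoke configuration used throughout the test suite runs 200 episodes
at step limit 8 with a compact network (128-bit fingerprints, hidden
sizes (32, 32), batch 32, Adam 1e-3, target sync every 10 episodes,
ε decrement 1/200) — a configuration chosen so a full deterministic run,
its byte-identical repeat, and a random-search control arm all complete in
a few minutes on one CPU while still showing clear learning progress
(the trained arm's final-reward distribution stochastically dominates the
random arm's; one-sided Mann–Whitney p < 0.01 at 200 episodes per arm, as
the test suite verifies). Production
settings (6000 episodes, step limit 16, 2048-bit fingerprints,
(1024, 512) hidden layers) are the defaults of `MDPConfig` and
`AgentConfig`.

## Known limitations

- The surrogate reward is a linear atom-count model; it cannot express
  pocket shape, pose strain, or any nonadditive binding effect.
- Aromatic systems are immutable except by substitution; edits that would
  de-aromatize or re-aromatize a ring are outside the action space.
- Generated molecules are limited to neutral C/N/O; no stereo-editing
  actions, tautomer or protonation enumeration.
- The numpy Q-network is single-threaded and CPU-sized; it is not meant
  for fingerprints or layer widths beyond the defaults.
- Docking through a real engine (QuickVina 2 / AutoDock 4 binaries) is
  supported by the adapter interface but not exercised by the test suite,
  which uses recorded-style reports.
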