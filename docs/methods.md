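# Methods

## Scope and model

`poseopt` implements the post-docking half of a structure-based virtual
screening pipeline.  The inputs are a receptor, a ligand (or a set of
docked poses of it), and a potential-energy backend; the outputs are
locally minimized complexes, binding energies, pose rankings, and the
standard docking/scoring/ranking-power statistics.  Pose *generation*
(the docking engine itself), structure preparation chemistry
(protonation, tautomers), solvation, and potential training are out of
scope: poses come either from an external engine via multi-model PDB or
from the synthetic decoy generator.

Units are kcal/mol for energies, Å for coordinates, and kcal/mol/Å for
forces everywhere in the API.  Optimizer convergence arithmetic is done
in atomic units (Hartree/Bohr, Bohr) so the thresholds can be stated
exactly in the convention quantum-chemistry packages print; conversions
use 1 Hartree = 627.5094740631 kcal/mol and 1 Bohr = 0.529177210903 Å.

## The CG-BS optimizer

Minimization uses nonlinear conjugate gradients with an Armijo
backtracking line search:

* direction update: Polak–Ribière⁺,
  `β_k = max(0, g_k·(g_k − g_{k−1}) / |g_{k−1}|²)`, with a restart to
  steepest descent every 3·N_free iterations (one sweep of the free
  coordinate count) and whenever the update fails to produce a descent
  direction.  The clamp to β ≥ 0 is the standard safeguard against
  direction reversal on non-quadratic surfaces.
* line search: first trial step scaled so the largest single-atom
  displacement is `initial_step` (default 0.05 Å); later searches start
  at twice the last accepted step, capped back at that geometric scale.
  Trials shrink by 0.5 until the sufficient-decrease condition
  `E(x+αd) ≤ E(x) + c₁ α g·d` holds (c₁ = 1e-4).  The curvature
  (second Wolfe) condition with c₂ = 0.9 is evaluated at the accepted
  point and recorded as a diagnostic; pure backtracking cannot enforce
  it, and accepting the first sufficient-decrease step is what keeps
  the method robust on machine-learned potential-energy surfaces, which
  are less smooth than ab initio ones.  A failed line search triggers a
  steepest-descent restart at a reduced step; two consecutive failures
  terminate with `converged = False` rather than raising.
* convergence: four criteria checked after every accepted step — the
  maximum and RMS over free atoms of the per-atom force-vector norms
  against 0.00045 and 0.0003 Hartree/Bohr, and of the per-atom
  displacement norms against 0.0018 and 0.0012 Bohr — all with `≤`.
  Before the first step the displacement criteria are defined as
  unsatisfied (there is no prior geometry).  Whether the original
  convention measures displacement per atom or per coordinate is
  ambiguous; the per-atom vector norm is used consistently for both
  forces and displacements.
* frozen atoms: their gradient components are masked out of every
  direction, so their coordinates are bit-identical on exit.  A start
  with exactly zero free-atom gradient returns immediately as
  converged (degenerate but well-defined).

Accepted-step energies are monotonically non-increasing by
construction (Armijo with a negative slope), which the tests assert on
every trace.

## Pocket truncation and region assignment

The receptor is reduced to every residue having at least one atom
within a radius of the ligand's geometric center.  The radius default
is 12 Å — the midpoint of the 8–15 Å range customary for this kind of
truncation — and values outside that range only warn, since the right
choice is system-dependent.  Residues are kept or dropped whole.
Backbone bonds severed by the truncation (peptide C–N, nucleotide
P–O3′; partners identified by residue adjacency and a 2 Å bond-length
sanity cutoff) are capped with a hydrogen at 1.09 Å along the former
bond vector.  Hydrogen caps rather than ACE/NME groups keep the
perturbation minimal, add no residues, and stay inside the H/C/N/O/S/F/Cl
element domain of the ANI-2x backend.  Nucleic-acid receptors are
handled by the same residue rule with nucleotides as residues.

Region assignment is per-atom and purely geometric: a pocket atom whose
minimum distance to any ligand atom (hydrogens included, atom centers)
is ≤ 2.5 Å joins the *active* region and is harmonically restrained to
its input position with weight 5 kcal/mol/Å²; all other pocket atoms
are *frozen* (sentinel weight −1).  The boundary comparison is
inclusive.  Ligand atoms carry no restraints.  The restraint functional
form is `E = k·Σ|r − r⁰|²` with no ½ factor, matching the convention in
which the weights are quoted; the −1 sentinel is a flag, not an energy
term, and frozen atoms still contribute to the base potential as a
static environment.  On disk the per-atom weight rides the PDB
temperature-factor column (two decimals), so prepared pockets remain
valid PDB files.

## Binding energy and ranking

After minimizing the restrained complex, the score is

    ΔE_bind = E_com − E_rec − E_lig

where all three terms are energies of the *base* potential (restraint
terms excluded): `E_com` on the optimized complex, `E_rec` and `E_lig`
single points on the pocket and ligand at their optimized in-complex
coordinates.  This rigid decomposition makes ΔE_bind exactly the
pocket–ligand cross-interaction for any pairwise-additive potential (an
identity the tests exploit); its known cost is that receptor/ligand
strain cancels out of the score.  An alternative mode
(`relax_components=True`) relaxes the pocket and ligand separately
before the single points, for cases where strain should count.  Poses
are ranked by ascending ΔE_bind with stable tie-breaking on input
order.

## Torsional restraints

A harmonic dihedral restraint `E = w·Δφ²` is provided, with Δφ the
signed difference to the target wrapped into (−180°, 180°] and the
analytic gradient distributed over the four atoms by the standard
normal-vector formulation.  The refinement protocol applies none by
default — only the capability is part of the optimizer contract — and
collinear consecutive triples raise rather than return an arbitrary
angle.

## Evaluation metrics

* **Receptor-anchored RMSD**: the least-squares (Kabsch) superposition
  is computed on receptor atoms only and applied to the predicted
  ligand; RMSD is then taken over ligand heavy atoms with no further
  fitting, so translation and rotation of the ligand within the pocket
  contribute at full magnitude.  Hydrogens are excluded from the RMSD
  because their docked placements are largely conventional; no
  topological-symmetry correction is applied.
* **Top-N analysis**: for a rank-ordered list of ≤10 pose RMSDs, the
  minima over the Top 1/3/5/10 prefixes are summarized; the
  first-success category is the smallest N whose minimum already equals
  the Top-10 minimum (tolerance 1e-9 on raw values, which is also exact
  on two-decimal table readbacks), and a system counts as a success
  when that category is ≤ 3.  Success rates are reported both exact and
  rounded to the nearest integer percent.
* **Correlations**: Pearson's R and Spearman's ρ (fractional average
  ranks for ties) delegate to scipy.stats behind the module surface;
  the test suite checks both against independent brute-force
  implementations to 1e-12.
* **Affinity conversion**: `ΔG = RT ln Ki` with
  R = 1.98720425864e-3 kcal/mol/K, T = 298.15 K, Ki referenced to 1 M;
  Kd values are treated identically.  Compound selection drops
  molecules with elements outside {C, H, O, N, S, F, Cl}, drops weak
  binders with ΔG above −4 kcal/mol, stratifies the rest into four Ki
  tiers (<10 nM, 10 nM–1 µM, 1–100 µM, ≥100 µM), and keeps at most 300
  per tier by seeded uniform subsampling.

Raw ΔG from the Ki conversion is used as the experimental variable in
correlations (no pKi transform); Spearman is invariant to that choice,
Pearson is not, and the convention is stated here for that reason.

## Benchmark tables

`poseopt.data` ships three small TSV tables from a published 23-system
benchmark (11 small-molecule–macromolecule and 12 peptide–protein
systems) comparing plain docking against docking followed by restrained
ML-potential refinement: per-system Top-1/3/5/10 lowest
receptor-anchored RMSDs, per-system Pearson R, and per-system
Spearman ρ.  These are *inputs* to the evaluation layer; every
aggregate — category histograms (2/15/1/5 refined vs 5/6/5/7 docking),
success rates (74% vs 48%), mean correlations, improved-system counts,
and per-system RMSD changes — is recomputed from the per-system values
at run time, never copied.  One rounding note: the 11 printed
docking-row Spearman values average to 0.307, which rounds to 0.31
while the source table prints an average of 0.30 (presumably computed
from unrounded values); the tests therefore compare that mean at
two-decimal precision (±0.01).

## Synthetic fixtures

The generators emulate the three inputs the pipeline needs without any
external engine:

* **Toy complexes**: receptor atoms on a cubic lattice with spacing at
  the Lennard-Jones pair minimum 2^(1/6)σ, jittered by 2% of σ so no
  two sites are exactly equivalent; the ligand is relaxed against the
  static receptor from a battery of exterior, interior and
  surface-tangential starts, and the deepest minimum becomes the native
  pose.  This makes the native basin the deepest sampled one by
  construction, so ranking tests have a well-defined right answer.  A
  1+1-atom spec reduces to the analytic LJ dimer.
* **Decoys**: rigid perturbations of the native pose — axis-angle
  rotation about the centroid (axis uniform on the sphere, angle
  uniform up to the cap) plus a translation of uniform magnitude up to
  the cap — optionally including the unperturbed native as the first
  pose.  The RMSD of any decoy to the native is bounded by
  `t_max + 2 R_g sin(θ_max/2)`, asserted as a property.
* **Screening tables**: Ki values log-uniform within each of the four
  affinity tiers (strongest tier floored at 0.1 nM, weakest capped at
  the −4 kcal/mol cutoff so all generated compounds survive the
  selection filters), with the predicted score equal to the exact
  RT·ln Ki energy plus Gaussian noise of chosen σ.  Under that model
  the population Pearson correlation is
  `sd(ΔG) / sqrt(sd(ΔG)² + σ²)`, which the tests use as the analytic
  attenuation target.

All generators take one explicit integer seed and touch no global
random state.

What these fixtures deliberately do not reproduce: chemical topology
and realistic conformational flexibility of ligands, heterogeneous
atom types, solvent, and the score landscape of a real docking engine.
Passing pipeline tests therefore demonstrate the *mechanics* —
restraints honored, frozen atoms immobile, energies decomposed and
ranked correctly, near-native poses recovered on a controlled surface —
not predictive accuracy on real complexes.

## Problem sizes and numerical choices

The pipeline tests run 10 toy complexes (8 receptor + 1 ligand atom,
10 poses each) with a 300-iteration optimizer budget and a fully frozen
pocket; the rigid pocket is used there because with a soft analytic
potential the rigid single-point ΔE_bind would otherwise reward poses
that pay receptor-deformation cost the decomposition cancels.
Correlation-attenuation checks use n = 500–1000 compounds.  The
optimizer's convex-quadratic budget (≤ 5·dim iterations to the analytic
minimum for dim ≤ 30) and the banana-valley benchmark (minimum located
within 1e-3 from the classic start) bound its behaviour on smooth
surfaces; both are asserted in the suite.

Known limitations: no symmetry-corrected RMSD; no periodic boundary
conditions; the ANI-2x adapter requires the optional torch/torchani
stack and validates its seven-element domain before touching it; the
line search guarantees sufficient decrease but not the curvature
condition; and non-convergence within `max_iterations` is reported in
the result object, not raised.
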