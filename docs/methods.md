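# Methods

## The model

A weakly aligned molecule acquires residual dipolar couplings (RDCs).
For a bonded pair P–Q with unit inter-nuclear vector **v** in the
molecular frame,

    D = D_max(P,Q) · Σᵢⱼ Sᵢⱼ vᵢ vⱼ ,     D_max = − µ₀ h γ_P γ_Q / (16 π³ r³),

where **S** is the Saupe order matrix — 3×3, symmetric, traceless —
describing the degree and direction of alignment.  Agreement between
calculated and experimental couplings is scored with the quality
factor Q = rms(D_calc − D_exp) / rms(D_exp); 0 is perfect.  One global
scale factor is fitted to the calculated couplings (least squares,
s* = ΣD_calc·D_exp / ΣD_calc²) because the absolute degree of
alignment, set by the medium concentration, is not predictable.  The
same s*, fitted on the working data, is applied unchanged when scoring
held-out couplings: the alignment magnitude is one physical quantity,
not a per-subset fit.

Under purely steric alignment **S** is computable from shape.  We use
a planar-barrier obstruction model: for each orientation **u** of the
barrier normal in the molecular frame (spherical grid, default 10°,
sin θ quadrature weights), the fraction of positions at which the
molecule fits between two parallel plates a distance L apart is
max(0, L − h(**u**))/L, with h the molecular extent along **u**
including bead radii.  The tensor is the weighted orientational
average S = ⟨(3 **u u**ᵀ − I)/2⟩.  Beads are one per residue at the
Cα (radius 3.8 Å) by default, or one per heavy atom (1.7 Å).  L
defaults to four times the maximal molecular radius; tighter spacing
strengthens alignment but only rescales and mildly reshapes the
tensor, and the absolute scale is refit downstream anyway.  The
predictor errors if the molecule fits in no orientation.  Tensors are
cached by a hash of the conformer coordinates because the search
re-uses them thousands of times.

For a molecule exchanging between conformations faster than the
measurement but slower than alignment, each conformer carries its own
tensor and the observed coupling is the unweighted average of the
per-conformer couplings over the ensemble (populations arise from
state multiplicity across pooled solutions, not per-member weights).

## Inter-domain angles

Two opening angles describe an adenylate-kinase-like three-domain
architecture (CORE, AMP-binding domain, ATP-binding LID), defined from
centres of mass of Cα residue windows (Beckstein-style):

* θ_AMPbd — vertex at a CORE window; rays to the CORE–LID hinge window
  and to an AMPbd window.
* θ_LID — vertex at the hinge window; rays to a second CORE window and
  to a LID window.

The E. coli enzyme's windows ship as the `ake` preset (CORE 90–100,
hinge 115–125, AMPbd 35–55, CORE 179–185, LID 125–153; the hinge and
LID windows share residue 125, as the definitions are printed).  The
windows are configurable so synthetic systems reuse the same
operations.

## The synthetic test system

Tests and validation run on a fully synthetic three-domain protein
(100 residues by default; N, Cα, and amide H per residue) whose two
binding domains swing about near-vertical hinge axes: AMPbd in a slab
below the CORE, LID in a slab above it, so any combination of opening
angles in θ_AMPbd ∈ [30°, 90°] × θ_LID ∈ [90°, 160°] — the ranges the
pool is required to cover — is reachable without steric overlap.  Because the lobes swing at
constant radius, the toy's overall dimensions are nearly
angle-invariant and the largest tensor eigenvalue varies only a few
percent; the shape signal the selection exploits is instead carried by
the tensor's orientation and asymmetry (the "open" (88°, 150°) and
"closed" (45°, 92°) presets differ by ~37% in relative Frobenius norm,
with a ~13° principal-axis rotation).  A real enzyme that compacts on
closing would change the eigenvalue magnitudes as well.

Pools are produced by rigid-body rotation of each mobile domain about
the axis through the centres of mass of its two flanking hinge
windows, with secant iteration (≤20 steps) until the measured angles
hit the requested targets within 2°.  A target angle is generally
reachable on two rotation branches; the generator prefers the branch
with the smallest rotation away from the seed, so neighbouring targets
belong to the same structural family and the pool varies smoothly with
angle.  The alternate branch is used only when the canonical one
produces an inter-domain clash (Cα–Cα < 3.0 Å between different
domains, ignoring residue pairs within 8 of each other in sequence,
whose proximity is covalently imposed at the hinges).  Unreachable or
clashing targets are skipped with a log entry and recorded in the pool
metadata.  Default pools use a 45×45 target grid (~2000 conformers)
with 0.7° Gaussian angular jitter.

What the toy does *not* emulate: internal (intra-domain) structural
heterogeneity.  Rigid hinge moves preserve intra-domain geometry
exactly — an invariant the tests assert — so two pool conformers at
the same opening angles are identical, whereas conformers from a
molecular-dynamics pool would differ in thousands of internal degrees
of freedom.  This matters for ensemble-size selection: the number of
members needed before the held-out fit plateaus grows with the
incoherent per-conformer variation inside a target basin, so plateau
sizes measured on this toy (2–8 members, see below) are smaller than
those of simulation-based pools of a real enzyme, where internal
heterogeneity inflates them.  Passing reconstruction tests here
demonstrates the machinery is correct, not that any particular
ensemble size is universal.

## The search

An ensemble is a size-N multiset of pool indices (repeats allowed, so
unequal populations are expressible at small N).  The genetic
algorithm holds a population of ensembles (1000 at full scale);
per step each ensemble yields a mutated copy (with probability =
mutation rate, one uniformly chosen member is replaced by a uniformly
chosen pool conformer) and a crossed copy (ensembles are randomly
paired; with probability = crossing rate one uniformly chosen member
is swapped between the pair).  All 3× candidates are scored by the
optimally scaled ensemble-averaged Q and the best third survives
(truncation selection, ties broken by candidate order for
determinism) — so the best score never worsens.  The mutation rate
starts at 100% and is divided by 1.001 per step; the crossing rate
starts at 2% and is multiplied by 1.001; both are clamped to
[0.001, 1] as a numerical safeguard.  After 1000 steps the best
ensemble is kept and the search repeats 200 times with independent RNG
streams (full-scale schedule).  On desk-scale problems the best Q
plateaus (<1% change per 100 steps) by about 400 iterations.

Scoring is O(population × couplings) per step: ensemble coupling sums
are maintained incrementally under single-member mutations and swaps
instead of re-gathering member rows.

The **scaled preset** used for tests and the validation experiments is
200 ensembles × 300 steps × 20 repeats on pools of ~2000 conformers —
chosen so a complete control experiment runs in minutes while leaving
the convergence and reconstruction properties intact at the stated
tolerances.

**Ensemble size** is selected by cross-validation: ten random 20%
holdout sets; for each, the GA runs on the remaining 80% (Q_work) and
the withheld couplings are scored as Q_free with the working-set scale
(20 repeats per set at full scale; 5 in the scaled protocol).  The
adequate size N* is the smallest N whose median Q_free lies within 5%
(relative, configurable) of the minimum over all N.

**Experimental-error propagation**: the search is repeated on many
copies of the data with independent Gaussian noise added to every
coupling (σ = 1.0 Hz by default, three times the typical 0.3 Hz
experimental uncertainty; 200 replicas at full scale), and basin
populations are summarized as mean ± sd across replicas.

## Distributions and populations

Pooled solutions are histogrammed over (θ_AMPbd, θ_LID) with 2° bins,
each member weighted 1/(members × solutions).  States are rectangles
in angle space; their populations are integrated weights.  Because a
selected ensemble reproduces a target basin's *average* couplings, its
members scatter in a basin around the target box rather than strictly
inside it; population accounting therefore uses regions larger than
the generating boxes:

* reconstruction experiments score target boxes dilated by 5°
  (one third of a typical 15° box);
* two-state recovery sweeps score half-plane basins splitting angle
  space at the midpoint of the gap between the state boxes, along the
  axis with the wider gap.

Both conventions are fixed properties of the procedures, not per-run
choices.  For comparison with single-molecule FRET, the ensemble is
projected onto a Cα–Cα distance between a user-chosen residue pair and
the open fraction is the weight above a distance cutoff; donor/
acceptor pairs and cutoffs are inputs with no defaults.

## Validation procedures

* **Scrambling** — permuting coupling values across residues preserves
  their distribution but destroys geometric information; the best
  attainable Q on scrambled data exceeds 0.9 (measured ≈ 0.98 on the
  toy at sizes 4–16) while the intact fit reaches Q ≈ 0.02.
* **Synthetic targets** — couplings are the population-weighted mean
  of cached conformer couplings over designed boxes (uniform within a
  box), plus Gaussian noise with σ a percentage of the largest
  coupling magnitude (ladder: 1, 3, 6%).
* **Alignment-magnitude error** — each conformer's couplings are
  multiplied by fold^d, where d is the conformer's Euclidean distance
  from the angle-range centre in normalized angle space (d = 1 at the
  range corners), for folds 2, 3, 10, 20, 50.  Scaling couplings is
  equivalent to scaling tensor magnitudes by linearity.  Fold 1 with
  identical seeds is the unperturbed reference.
* **Population recovery** — two-state targets with the closed fraction
  swept over [0, 1] (1% steps at full scale; 5% in the scaled runs)
  are reconstructed at N = 16 per error fold.  With exact tensors the
  per-point deviations measure 0.00–0.05 (granularity 1/320 at the
  scaled run counts); they grow with the fold error overall, though
  the per-fold maxima fluctuate between adjacent large folds.

Measured on the scaled preset (seed 1): the unimodal 15×15° target at
1% noise plateaus at N* = 2–4 with the recovered population within 0.1
of the truth; the four-state target plateaus at N* = 8.  As discussed
above, these plateau sizes reflect the rigid-hinge pool's lack of
internal heterogeneity and would shift upward for simulation-based
pools.

## Numerical choices and edge cases

* Missing coupling uncertainties default to 0.3 Hz.
* The SVD tensor fit requires ≥5 couplings and a rank-5 direction
  design matrix; degeneracy is reported, not silently regularized.
* An all-zero calculated (or experimental) coupling vector raises
  rather than dividing by zero; in vectorized GA scoring a zero-norm
  average scores s = 0, Q = 1.
* Structures lacking amide protons (typical X-ray files) get an H
  placed 1.02 Å from N, anti to the bisector of the N→Cα and
  N→C(prev) directions; affected residues are logged.
* A simple Cα-virtual-dihedral secondary-structure assignment can
  exclude loop residues from the working couplings; explicit
  include/exclude lists override it.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning; identical seeds give
  byte-identical results.

## Known limitations

* One steric predictor (the planar-barrier model); electrostatic
  alignment and alternative shape predictors are out of scope, though
  the tensor-prediction interface is pluggable.
* Rigid-hinge pools carry no internal heterogeneity (see above) and no
  force-field energetics beyond a hard-sphere clash filter.
* The method recovers equilibrium distributions; nothing kinetic
  (pathways, rates) can be inferred from it.
* Couplings are computed for fixed-distance bonded pairs only; no
  dynamic averaging of the bond length.
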