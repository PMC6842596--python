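# Methods

## Scientific scope

This package models the elementary step of nucleic-acid duplex
separation at a single-strand/double-strand (ss/ds) junction.  Opening
of a Watson–Crick base pair is stepwise and asymmetric: one of the two
bases unpairs and unstacks first ("flips out"), leaving a dangling-base
intermediate, before the partner follows.  Which base goes first — the
one at the 5′ terminus of the junction or its partner at the 3′
terminus — depends on helix form (A vs B) and on sequence, and this
asymmetry predicts how efficiently a helicase of given directionality
unwinds a duplex (the h-unwind index).  The pipeline is:

1. build an idealized all-heavy-atom A-form (RNA) or B-form (DNA)
   duplex from sequence (`helix_builder`);
2. derive a structure-based (Gō-type) Hamiltonian whose global minimum
   is that native structure (`sbm_forcefield`);
3. sample reversible unzipping with Langevin dynamics under a constant
   force applied between the terminal 5′/3′ hydroxyl oxygens, mimicking
   a constant-force optical-tweezer experiment (`langevin_engine`);
4. classify each frame's junction base pair as CLOSED, FLIP5 (5′ base
   out ⇒ 3′-dangling intermediate), FLIP3, or OPEN, and segment
   opening/closing events with pathway labels (`junction_states`);
5. remove the mechanical bias by exponential reweighting and estimate,
   per nearest-neighbor (NN) context, the free-energy difference
   g = k_BT·ln(W_FLIP5/W_FLIP3) between the two dangling intermediates,
   with moving-block bootstrap errors (`thermo_stats`);
6. turn a g table into the h-unwind index of a duplex/helicase pair
   (`hunwind_score`);
7. analyze fluorescence unwinding time courses as saturating
   exponentials and compare substrates by relative amplitude and
   initial velocity (`assay_kinetics`).

`surrogate_data` generates synthetic inputs with exactly known ground
truth for every analysis stage; `pipeline` bundles steps 1–5 into one
protocol so scripts and tests run identical computations.

## Idealized duplex geometry

Bases are planar idealized rings (regular hexagons/fused pentagons,
1.38 Å aromatic bonds) placed in a canonical pair frame with the
purine-N1⋯pyrimidine-N3 distance at 2.90 Å; the two glycosidic C1′
atoms are pinned to sequence-independent positions so all WC pairs are
isomorphous.  Strand 2 geometry is the in-plane dyad image of strand 1.
The backbone is generated by constraint satisfaction: the phosphate of
the next residue is placed by the exact helical step (twist, rise), the
O3′–P linkage closes at 1.60 Å by construction, and sugar atoms bridge
the fixed anchors with near-tetrahedral spacing.  Two non-obvious
choices matter:

* **No native angle may approach 180°.**  Dihedral forces are singular
  at collinearity; an early version of the sugar geometry placed
  C5′–C4′–C3′ at 172° and injected energy through that singularity.
  The branch biases keep the largest native angle near 148°.
* **Pair reference point.**  "Rise" is the axial (z) separation of the
  C1′-midpoint reference points, exact by construction; the Euclidean
  separation exceeds it for displaced (A-form) helices.

Helix parameters are standard fiber values: A-form 32.7°/2.81 Å with
−4.4 Å x-displacement and 19° inclination; B-form 36.0°/3.38 Å, no
displacement.  The A-form displacement and inclination are what make
the 5′-terminal base of a junction less buried than its 3′ partner —
the geometric origin of the A-form opening asymmetry — and the test
suite asserts this both on lateral centroid offsets and on
contact-count burial.  Hydrogens, sugar pucker, propeller twist and
sequence-dependent fine structure are omitted: the structure-based
Hamiltonian only needs a self-consistent reference state.

## Structure-based Hamiltonian

Functional forms: harmonic bonds k_b(r−r₀)² and angles k_θ(θ−θ₀)²,
cosine dihedrals k₁(1−cos(φ−φ₀)) + k₃(1−cos 3(φ−φ₀)) (one per central
bond), 12-6 Lennard-Jones native contacts with the minimum pinned at
the native separation, and a purely repulsive excluded-volume wall for
all remaining nonbonded pairs.  Reduced units: contact depth ε_C ≡ 1,
lengths in Å, masses 1, k_B = 1.  Default stiffnesses k_b = 100 ε/Ų,
k_θ = 40 ε/rad², k₁ = 1, k₃ = 0.5, ε_ex = 1 (bond ≫ angle ≫ dihedral ≈
contact); all exposed in `FFParams`.

The excluded-volume term is force-shifted to zero at its cutoff and the
per-pair cutoff never exceeds the pair's native separation, so the
native structure is an *exact* stationary point (max |F| ≤ 1e-6) and an
exact minimum of the contact sum (E_contact = −ε_C·N_contacts); both
are asserted in tests together with finite-difference force checks at
1e-4 relative.

**Contact map.**  Heavy-atom pairs within 4.5 Å, excluding pairs within
three covalent bonds and same-chain pairs closer than one intervening
residue — *except* that base–base pairs of directly adjacent residues
are retained.  These are the stacking contacts; they carry the
purine/pyrimidine asymmetry (a purine's larger ring buries more
contacts than a pyrimidine's), and without them the model loses the
sequence dependence of junction opening: in B-DNA the CC/GG junction
then wrongly prefers flipping the guanine.  Occlusion-based ("shadow")
contact-map algorithms used by some structure-based model generators
are not implemented; the cutoff map plus the stacking rule is this
package's documented simplification.

**Pulling.**  A constant force f_C acts along the line joining the 5′O
of chain 1 residue 1 and the 3′O of the chain-2 terminal residue (the
two hydroxyls of the same terminal base pair), contributing −f_C·x to
the potential with equal and opposite forces on the two atoms.  Unit
mapping: the calibrated simulation temperature represents 296 K, where
k_BT = 4.09 pN·nm, so 14 pN ↔ 3.42 k_BT/nm and β·f_C is fixed at
0.342 Å⁻¹ independent of the reduced temperature.

## Langevin dynamics

BAOAB splitting (velocity Verlet at γ = 0) with dt = 0.002 and γ = 1
by default; the excluded-volume pairs use a neighbor list rebuilt every
25 steps with a 1 Å skin.  Validated limits: harmonic-bond period to
0.1%, NVE energy drift ≤ 1e-4 relative over 1e5 steps, configurational
variance of a thermostated oscillator to 2%, kinetic-energy
equipartition of the full duplex to 2%.  Runs are bit-reproducible for
a fixed seed within a given numba build.

**Tether wall.**  Under a constant pulling force, complete strand
dissociation is absorbing (x grows without bound), so equilibrium
hopping requires the finite extension of a real tweezer construct.  A
flat-bottom harmonic wall caps x (5 nm for hexamers, off by default);
it only acts beyond both basins and leaves the junction statistics
untouched.

**Temperature calibration.**  The reduced temperature that corresponds
to the experimental condition is chosen by scanning a grid and keeping
the temperature whose trajectory has the most balanced product of
folded (x < x₀+0.65 nm) and unfolded (x > x₀+1.0 nm) occupancies with
at least a minimum number of transitions.  For the hexamers at 14 pN
this lands near T ≈ 3.4 (A-RNA) and T ≈ 2.8–3.0 (B-DNA).  At desk
scale the "unfolded" basin is the partially unzipped extended branch
(junction one or more pairs in); all-six-pair unzipping is not a
separate basin at this force and size.  The folded/unzipped hopping,
the bimodal end-to-end histogram and tens of transitions per
~10⁶-step run reproduce the two-basin phenomenology at reduced scale.

## Junction states and events

Three smoothed distance channels per junction position (default window:
6 saved frames = 300 integration steps): WC pairing (N1–N3), 5′
stacking (chain-1 base-ring centroids k, k+1) and 3′ stacking (chain-2
partner and inward neighbor).  A channel is disrupted when it exceeds
its native value by an offset (pairing 2.5 Å, stacking 3.0 Å) with
0.5 Å hysteresis.  A base counts as flipped out only when it is *both*
unpaired and unstacked — the stepwise mechanism's definition — which
matters because the pulling force stretches junction stacking even
while the pair is closed; with purely stacking-based rules, closed
frames under tension are misclassified as intermediates.  The stacking
offset (3.0 Å vs the generic 2.5 Å) was set from the separation of
stacked/unstacked channel distributions in prototype runs.  States:
CLOSED, FLIP5 (5′-terminus base out ⇒ 3′-dangling intermediate), FLIP3
(mirror), OPEN (both out).  The junction is the first non-OPEN pair
from the pulled end.

Events are CLOSED→OPEN transits (or the reverse) of a pair's debounced
state series (minimum dwell: one smoothing window); the pathway is the
longest-dwelling intermediate, with exact ties labeled `direct` and
excluded from 5′/3′ tallies.  Only pulled-side junction events enter
NN statistics: far-end fraying and interior-bubble excursions have the
opposite context orientation (the strand presenting the 5′ terminus
differs) and are filtered out.

## Reweighting and free energies

Frame weights w_i ∝ exp(−βf_C·x_i) remove the pulling bias
(βf_C = f_pN/4.09 per nm); the per-context free-energy difference is
g = k_BT·ln(W_FLIP5/W_FLIP3) over junction frames, positive when the
3′-dangling intermediate dominates the unbiased ensemble.  Contexts
written `XY/X'Y'`: junction pair first (chain-1/5′-terminus strand on
top), inward neighbor second; strand-swapped duplexes get distinct
labels (CC/GG vs GG/CC).  Contexts lacking one intermediate are
reported as unobserved (NaN), never zeroed.  Errors come from a
moving-block bootstrap (default block: 5× the junction-state
autocorrelation time; n_boot configurable, 1000 for final tables, less
in quick protocols), which matches the delta-method closed form on
i.i.d. surrogates and scales as 1/√n.

Desk-scale results (hexamers, ~1.6×10⁶ production steps): A-RNA gives
g > 0 for every sampled context of the default panel — the 5′ base
flips preferentially — while B-DNA gives g(CC/GG) > 0 and
g(GG/CC) < 0: the pyrimidine flips first, so the preference follows
the sequence and flips with strand swap.  These are sign-level,
stochastic statements; magnitudes depend on the reduced model's
contact statistics and are not transferable numbers.

**Default sequence panel.**  RNA: GCGCGC and CCGCGC (contexts GC/CG,
CG/GC and CC/GG, with the opening pair sampled at the best-statistics
junction positions); DNA: CCGCGC and its strand swap GGCGCG (CC/GG vs
GG/CC).  For RNA contexts with a purine at the junction 5′ terminus
(e.g. GG/CC) the model's two biases — the A-form geometry favoring the
5′ flip and the purine's larger stacking surface opposing it — nearly
cancel, and the sign of g is not resolved at these run lengths
(estimates between roughly −1 and +1.3 k_BT across seeds).  This is a
known limitation of the reduced model: resolving those contexts needs
either longer ensembles or a finer-grained Hamiltonian, so the default
panel samples the contexts the model can resolve.

## h-unwind

For a helicase tracking one strand, each junction's table entry gives
the probability that the *displaced* strand's base is the flipped one:
p = σ(s·g/k_BT) with s = +1 when the displaced base's flip is that
context's FLIP5 intermediate (displaced strand presents the junction
5′ terminus, as for 3′→5′ helicases) and s = −1 otherwise.  h-unwind
is the mean of p over the N−1 junction steps in the travel direction
(a geometric-mean aggregate is available for sensitivity analysis);
it is 0.5 exactly for an all-zero table and increases monotonically
with any g moved toward displaced-base flipping.  The designed
constructs hold a 21-bp duplex whose displaced strand is homopurine
((AG)-repeat) or homopyrimidine ((TC)-repeat) for either helicase
polarity; the Pu/Py members of a pair share the same double helix with
swapped roles.  With any pyrimidine-flip-favoring table — the uniform
1 k_BT toy table (closed form h = 1/(1+e∓1) ≈ 0.731/0.269) or the
simulation-estimated DNA table applied to G/C homopolymer constructs —
the homopyrimidine-displaced constructs outrank their homopurine
twins for both directionalities.

## Synthetic data

* `junction_model` — a reversible four-state jump process on the
  stepwise cycle CLOSED↔FLIP5↔OPEN↔FLIP3↔CLOSED with rates
  ν·√(π_b/π_a), which satisfies detailed balance for any prescribed
  stationary distribution π (Kolmogorov's loop condition holds on the
  4-cycle).  Emissions are Gaussian distance channels around per-state
  means (disrupted channels +8 Å, SD 0.35 Å) and a per-state
  end-to-end x.  It reproduces the statistical structure the
  free-energy and bootstrap analysis assumes — discrete states,
  autocorrelation, reversibility — but not the continuous transition
  paths, force propagation or junction migration of the MD engine, so
  surrogate-based passes validate the estimators, not the physics.
* `biased_two_state_sampler` — two x values with equal unbiased weight
  sampled under exp(+βf·x); reweighting must return 0.5/0.5 (exactly,
  by algebraic cancellation, in expectation).
* `synth_unwinding_trace` — F(t) = baseline + A(1−e^(−kt)) + Gaussian
  noise, in minutes, mimicking quenched-fluorophore unwinding assays
  with ~25–300 min plateaus.  Real traces have drift, photobleaching
  and lag phases that the generator omits; the analysis reports ratios
  (relative amplitude and initial velocity), which are robust to the
  single-exponential idealization on saturating traces.

## Problem sizes and reproducibility

Default protocol sizes (chosen for a single desktop CPU): hexamer
duplexes (~250 heavy atoms), four calibration runs of 2.5×10⁵ steps
per nucleic type and production runs of 1.6×10⁶ steps (stride 50 →
32 000 frames), giving tens of folded/unfolded transitions and
10³–10⁴ junction-intermediate frames per sampled context.  The full
published workflow corresponds to much longer ensembles covering all
16 NN contexts; the statistics here are scaled down accordingly and
every sequence/temperature/length is exposed as a parameter.  All
stochastic components (engine, surrogates, bootstrap) take explicit
seeds.

## Known limitations

* Idealized geometry: no sugar pucker, propeller, or sequence-specific
  backbone fine structure; magnitudes of g are model-specific.
* Interior bubble formation and long duplexes are out of scope; only
  ss/ds junction dynamics are analyzed.
* No electrostatics, solvent or ions; noncanonical kinetic traps are
  absent by construction.
* The h-unwind operationalization (logistic map of g, arithmetic mean
  over steps) is this package's realization of "inversely related to
  the stacked displaced-strand population"; terminal steps use the
  same rule as interior ones.
* Helicase kinetics (step size, ATP coupling, active/passive
  mechanisms) are not modeled; kinetic traces are analyzed, not
  predicted.
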