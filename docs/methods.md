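# Methods

## Model

Each residue is a single bead at its Cα position (mass 110 Da; zinc ions
are explicit 65.4 Da beads). The potential is minimally frustrated: only
residue pairs in contact in the native complex attract.

* **Native contacts.** A pair (i, j) is native if any heavy-atom pair is
  within 4.5 Å in the native structure (Cα-based criterion as fallback for
  Cα-only inputs; both cutoffs configurable), with |i−j| ≥ 3 for
  intramolecular pairs. Each contact carries a 12-10 well
  U = ε_ij[5(r₀/r)¹² − 6(r₀/r)¹⁰] with r₀ the native Cα distance.
* **Sequence flavoring.** ε_ij = ε₀ · w(a_i, a_j), where w is a symmetric
  20×20 residue-pair weight matrix normalized so the mean weight over the
  model's contacts is exactly 1 (so ε₀ sets the mean well depth and the
  flavoring only redistributes it). The shipped matrix derives pair weights
  from Kyte–Doolittle hydropathies, w_ij ∝ exp[0.05 (h_i + h_j)],
  reinforcing hydrophobic–hydrophobic contacts ~6× over
  hydrophilic–hydrophilic ones; a uniform matrix is available and is used
  in most tests. This is a documented surrogate for statistical
  contact-energy matrices, chosen so the package carries no table whose
  provenance it cannot state; the normalization contract makes results
  insensitive to the overall scale of any replacement matrix.
* **Bonded terms.** Virtual bonds between consecutive residues are held at
  their native lengths by SHAKE (so the bond energy is reported as zero
  during dynamics; a harmonic term with k = 100 kcal/mol/Å² exists for
  unconstrained energy evaluation). Angles: harmonic, k_θ = 20
  kcal/mol/rad², native reference. Dihedrals: k₁(1−cos Δφ) + k₃(1−cos 3Δφ)
  with k₁ = 0.4, k₃ = 0.2 kcal/mol, native reference. These stiffnesses are
  conventional Cα-model values; they are configurable on the compiled
  system.
* **Excluded volume.** All non-native, non-bonded pairs (intra |i−j| ≥ 3;
  all inter) repel as ε_rep(σ/r)¹² with σ = 4.0 Å, ε_rep = 1 kcal/mol.
* **Electrostatics.** Optional formal charges (Lys/Arg +1, Glu/Asp −1, His
  neutral, Zn +2) interact through a Debye–Hückel potential
  k_C q_i q_j e^{−r/λ_D}/(ε_r r) with ε_r = 80 and λ_D from the ionic
  strength (13.7 Å at 0.05 M, 300 K); I = 0 gives unscreened Coulomb/ε_r.
  Native pairs feel electrostatics in addition to their well; this choice
  (rather than excluding them) keeps charged/uncharged models identical
  except for the one added term.
* **Cutoff and boundaries.** All non-bonded terms are truncated at 25 Å by
  potential shifting (U → U − U(r_c)), under the minimum-image convention
  in a cubic box whose edge must exceed twice the cutoff. Shifting (vs
  switching) was chosen to avoid energy drift at the truncation radius;
  forces are continuous everywhere except the negligible cutoff
  discontinuity of the force itself.
* **Zinc sites.** Structural ions are tethered to their coordinating
  residues (heavy atoms within 3 Å in the native structure) by harmonic
  distance restraints, k = 50 kcal/mol/Å² at the native distances.

## Sampling

Langevin dynamics uses a BAOAB splitting: half kick, half drift + SHAKE,
exact Ornstein–Uhlenbeck velocity refresh + RATTLE, half drift + SHAKE,
half kick + RATTLE. At zero friction this is velocity Verlet (energy drift
< 0.1 % over 10⁵ small steps in the tests). Defaults follow the standard
coarse-grained protocol: 15 fs timestep, friction 0.1 ps⁻¹. SHAKE converges
to 1e-8 relative bond-length tolerance (500-iteration cap, hard error on
failure); saved frames satisfy constraints to < 1e-6 Å. Identical
topology + config + seed reproduces trajectories bit-for-bit; the
integrator runs in numba kernels whose RNG is seeded per segment from the
user seed.

Pair interactions are evaluated over pair tables precomputed once per
topology (complete enumeration with the cutoff applied per evaluation)
rather than through a rebuilt neighbor list; at the system sizes this
package targets (tens to a few hundred beads) the full table is faster and
has identical physics.

Replica exchange runs independent Langevin segments per temperature slot
and attempts neighbor swaps every 1000 steps (alternating even/odd pairs)
with the Metropolis factor min(1, exp[(β_i − β_j)(U_i − U_j)]);
configurations swap and velocities rescale by √(T_new/T_old). The default
ladder is geometric, eight replicas spanning 270–400 K.

## Thermodynamic analysis

WHAM is implemented binlessly: self-consistent free-energy offsets f_k give
every pooled sample a normalized weight at any query temperature, so any
per-sample observable can be reweighted without committing to a histogram.
From the weights: C_V(T) = (⟨U²⟩−⟨U⟩²)/(k_BT²); free-energy surfaces
F = −k_BT ln P anchored to zero over occupied bins with empty bins masked;
and the melting temperature, located first at the C_V peak and then refined
to the temperature where the reweighted bound probability crosses ½.

The dissociation constant treats the box as one interacting pair at
effective concentration C_eff = 1/(N_A V): K_D = C_eff P_U²/(1−P_U) at
300 K. The default unbound definition is "no native intermolecular contact
formed" (P_U = P[N_inter = 0]); for barrierless binding profiles, where
partially bound intermediates would otherwise count as unbound, the
complement rule P_U = 1 − P[N_inter ≥ threshold] is available. Both are
exposed; the default is documented per study. Uncertainties follow the
half-split convention (first half vs second half of the data).

## Kinetic analysis

Specific (native intermolecular, ±1.0 Å criterion) and nonspecific (10 Å
Cα, native pairs excluded so the definitions are disjoint) contact counts
are smoothed with a 15-ps centered running average, then each frame is
labeled U (neither contact type), CC (nonspecific only) or B (N_inter at or
above the per-model bound threshold). Frames with intermediate specific
contact counts inherit the previous unambiguous label (CC at the start) —
intermediates are bookkeeping, not a fourth state. Direct U↔B label changes
are split through a zero-length CC visit so the transition graph stays
nearest-neighbor.

Rates: k_TS = N_TS/t_tot counts completed U→B plus B→U passages (at T_m
this is half the sum of binding and unbinding frequencies);
k_cap = 1/MFPT(U→CC); k_esc = N_esc/T_CC and k_evo = N_evo/T_CC with T_CC
the total collision-complex residence time, so the evolution fraction
N_evo/(N_evo+N_esc) equals k_evo/(k_evo+k_esc) identically. Two MFPT
conventions are reported side by side, because transitions between CC and B
traverse unmodeled intermediates and the effective MFPT depends on both
endpoints: *first-passage* times (elapsed time from entering X to first
arrival in Y; defined for every ordered pair and additive for Markov
chains, used for k_cap) and *conditional exit* times (mean residence of an
X episode given its next state is Y; the "time spent in the initial state
before the transition" convention). On/off rates come from the mean
residence times of the unbound/bound macrostates (CC flickers included in
the span between arrivals).

## Calibration protocol

Gō models transplanted from a folded complex over-stabilize the unbound
IDP, so calibration is two-stage and is repeated after charge assignment:

1. **λ_intra** — bisection over [0.1, 1.5]; each evaluation is a fixed-
   length unbound Langevin run whose mean residual helicity is compared to
   the target (default tolerance 0.05). Helicity of a residue is
   operationalized as: its native (i, i+4) contact is formed *and* the
   Cα(i−1..i+2) pseudo-dihedral is within 40° of native — a Cα-resolution
   proxy chosen because secondary-structure assignment needs backbone atoms
   the model does not have. Per-residue profiles or a mean target are both
   accepted.
2. **λ_inter** — log-space bisection; each evaluation is a REX run + WHAM
   K_D at 300 K, accepted within one order of magnitude of the target. The
   computed K_D is very sensitive to small λ_inter changes, which is why the
   acceptance window is a decade, not a percentage.

Production runs then use the melting temperature, first estimated from
REX/WHAM and fine-tuned with short production probes until bound and
unbound occupancies are within 35–65 % (warning at worse than 80/20), so
both rate directions are well sampled.

## Charge census

SASA is Shrake–Rupley (960 sphere points, 1.4 Å probe, element radii),
via biotite, so the census is deterministic. Binding-site residues lose
strictly more than 1.0 Å² SASA upon complexation; surface residues exceed
5 % relative accessibility against shipped per-residue maximal-SASA
reference values (Tien-style theoretical maxima); the vicinity is the
surface within 15 Å minimal Cα–Cα distance of the IDP, minus the binding
site (disjoint by construction). Counts cover Lys/Arg/Asp/Glu with His
neutral.

## Synthetic data: what it emulates and what it does not

* **Toy complexes** are ideal-geometry helix/coil Cα traces (plus pseudo-Cβ
  atoms for SASA work) with designed charge patterns, emitted as standard
  PDB with machine-readable ground truth (charges, net charges, and the
  contact list from an independent O(n²) scan). The standard binding toy
  packs a +4 substrate helix against a −4 IDP helix (11 intermolecular
  contacts at the 7.5 Å Cα criterion). Toys emulate the *structure* of the
  inputs — two-chain complexes with intra/inter contacts and complementary
  charges — not real sequences, helicities, or interface sizes. Passing
  tests therefore demonstrate correctness of the machinery and the
  *direction* of electrostatic effects, not quantitative rates of any real
  complex.
* **Markov chains** (Gillespie, discretized at the frame spacing) provide
  exact-rate oracles for the full state-assignment → rates path, including
  emitted contact-count series consistent with the labels.
* **Thermo samples** are exact Boltzmann draws from harmonic and two-level
  models, giving closed-form oracles for WHAM, C_V, occupancies, T_m and
  K_D.

## Study conditions for the toy analyses

Fixed once in `idpgo.studies.ToyStudyConditions` and shared by the analysis
scripts, the acceptance test and `scripts/acceptance.py`: 60 Å box (C_eff =
7.69 mM, large enough for the 25 Å cutoff and small enough that binding
events are frequent), base ε₀ = 1.0 kcal/mol with default flavoring,
λ_intra = 1, λ_inter = 1.5 (set so the uncharged toy melts inside the
270–400 K ladder), bound threshold N_inter ≥ 7 of 11, replica exchange
4×10⁵ steps per replica (6 ns), production 2×10⁶ steps (30 ns) saved every
0.3 ps, 15-ps smoothing. These lengths resolve of order 20–60 capture and
evolution events per model — enough for robust direction-of-effect
comparisons with fixed seeds; quantitative reproduction of
experimentally calibrated systems requires the full protocol at
thousands-fold longer sampling and experimentally derived calibration
targets, which this repository's analyses do not attempt.

## Numerical choices and degenerate inputs

Energies in kcal/mol, lengths in Å, times in ps, k_B = 0.0019872
kcal/mol/K, k_C = 332.0636 kcal·Å/(mol·e²). WHAM iterates to max|Δf| <
1e-10 (log-sum-exp throughout; hard error with diagnostics on
non-convergence). Degenerate cases are explicit errors, not silent values:
overlapping particles in the force field, missing Cα or unknown residue
names in PDB input, P_U ∈ {0,1} in the K_D estimator, no P_bound = ½
crossing in T_m location, zero completed collision episodes in the
evolution fraction. Rates whose transition count is zero are reported as 0
and flagged. The two-particle fixtures used for Boltzmann-statistics tests
use a 10 kcal/mol well so that basin escape is negligible on the test run
length and the quadrature oracle's normalization window matches the
sampled ensemble.

## Known limitations

* Cα resolution overstates salt screening of electrostatic steering and
  cannot resolve side-chain packing or desolvation barriers (the 12-10 well
  has none).
* The collision-complex state is defined by a single nonspecific-contact
  cutoff; it is not an "encounter complex" in the experimental sense.
* MFPTs between CC and B depend on both endpoints because real transitions
  traverse intermediates the three-state model does not represent; both
  reported conventions inherit this.
* K_D assumes exactly one pair per box (no aggregation, no activity
  corrections).
* The flavoring matrix is a hydrophobicity-derived surrogate, not a fitted
  statistical potential; with mean-normalization its influence on toy
  results is modest, but transplanting quantitative conclusions to real
  sequences would require a vetted matrix.
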