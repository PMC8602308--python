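# Methods

This note defines the model implemented in `tsforge`, the conventions
and defaults behind every number the package produces, and the scope of
the synthetic generators used for verification.

## 1. Molecular-mechanics model (`tsforge.mmcore`)

Energies are in kJ·mol⁻¹, distances in Å, angles in degrees.

**Stretch** ½·k_b·(r − r₀)² with k_b in kJ·mol⁻¹·Å⁻².

**Bend** ½·k_a·(θ − θ₀)² with θ in degrees and k_a in
kJ·mol⁻¹·deg⁻² (degree-based constants keep the YAML files readable;
typical magnitudes are therefore ~0.05–0.12).

**Torsion** ½·[V₁(1 + cos φ) + V₂(1 − cos 2φ) + V₃(1 + cos 3φ)],
the standard three-term Fourier form. The analytic gradient uses the
Blondel–Karplus derivative formulas, which are singularity-free away
from collinear bond geometries.

**van der Waals** Buckingham exp-6,
E = ε·[1.84·10⁵·e^(−12 r/r*) − 2.25·(r*/r)⁶], with combination rules
ε_ij = √(ε_i ε_j) and r*_ij = (r*_i + r*_j)/2. The exp-6 form turns
over at small r (x_c = r/r* ≈ 0.302); below that universal turnover the
potential continues as a steep quadratic wall matched in value, keeping
the energy surface C¹ and repulsive everywhere at short range.

**Electrostatics** Coulomb q_i·q_j·1389.35/(ε_d·r) (kJ·mol⁻¹ for
charges in e and r in Å), with dielectric ε_d = 1.0 by default.

Nonbonded terms act on pairs separated by three or more bonds (1-4 and
beyond, at full strength); 1-2 and 1-3 interactions are absorbed into
the bonded terms.

Hessians are obtained by central finite differences of the analytic
gradient (step 10⁻⁴ Å) and symmetrized. Minimization is L-BFGS-B on the
analytic gradient; convergence is reported against an RMS-gradient
tolerance (default 0.01 kJ·mol⁻¹·Å⁻¹). Superposition RMSD uses Kabsch
alignment (proper rotations only, so enantiomeric geometries do *not*
superpose — deliberately, since chirality is the object of study).

## 2. TSFF parameterization (`tsforge.q2mm`)

A reference structure supplies its geometry (internal coordinates), a
Cartesian Hessian and atomic charges. For a transition state the
reference Hessian has exactly one strongly negative eigenvalue (the
reaction mode); `modify_ts_hessian` replaces it by +ω
(default ω = 4184 kJ·mol⁻¹·Å⁻², i.e. 1000 kcal·mol⁻¹·Å⁻²), so the
force field is trained to treat the TS as a minimum along the reaction
coordinate — the Q2MM device that makes a TS representable by a
conventional force field. An eigenvalue is "negative" below
−ε_neg = 1.0; matrices with two or more such eigenvalues are rejected
as not first-order saddles.

The penalty is a weighted sum of squared residual classes evaluated at
the *reference geometry*: bond lengths, bend angles, torsions (wrapped
into (−180°, 180°]), Hessian elements projected into the reference
eigenbasis (diagonal vs the modified eigenvalues, plus off-diagonal
upper-triangle elements, which should vanish), and charges. Default
weights (bond 100, angle 2, torsion 1, Hessian 0.03/0.03, charge 30 —
per Å, degree, kJ·mol⁻¹·Å⁻² and e respectively) balance the typical
magnitudes of the classes; all are configurable.

Fitting is Levenberg–Marquardt over a named subset of parameters
(`PenaltyConfig.theta`, keys like `stretch/NU,CT/k`). Positive-by-
definition parameters (force constants, r₀, ε, r*) are optimized in
log-space. The Jacobian is forward-difference (relative step 10⁻⁴);
damping is multiplied/divided by 3; only penalty-decreasing steps are
accepted, so the reported penalty trace is non-increasing by
construction; a Nelder–Mead fallback handles the rare stalled case.
`internal_validate` reports the squared Pearson correlation between
MM and reference observables pooled per class.

## 3. TS assembly (`tsforge.assembly`)

A template is a core TS structure carrying dummy atoms (element `Du`)
marking anchor sites, each typed by the fragment class it accepts, plus
the product configuration (R/S) and allyl isomer (exo/endo) labels.
Fragments carry exactly one dummy marking their attachment vector.
`attach` deletes both dummies, joins the two real anchor atoms along
the host's dummy direction at the force-field equilibrium length
(1.5 Å fallback without a force field), and picks the attachment
torsion by a 30° coarse scan refined to 1° (±15° around the best coarse
point), scoring by MM energy (or a clash heuristic without a force
field) and rejecting geometries with contacts under 0.7 Å.
`enumerate_ts` fills all sites in deterministic (sorted) order for
every template, drops templates that cannot be assembled, and fails
only if a whole configuration class (R or S) becomes empty.

## 4. Conformational search (`tsforge.conformers`)

Rotatable bonds are acyclic, non-terminal and never the forming bond.
Each Monte-Carlo step perturbs 1–3 torsions of a randomly chosen pool
member by 30–180° (random sign), minimizes, and accepts the result into
the pool if it lies within an energy window (default 21 kJ·mol⁻¹,
roughly matching a 5 kcal·mol⁻¹ window) of the best energy found;
duplicates are detected by simultaneous energy (0.1 kJ·mol⁻¹) and
superposition-RMSD (0.25 Å) agreement. The defaults (40 000 steps in
the CLI) follow common practice for production searches; the test
systems need only hundreds of steps. All randomness flows from one
`numpy` generator, so results are bit-reproducible per seed.

## 5. Selectivity and proofreading (`tsforge.selectivity`, `tsforge.proofread`)

Each pathway ensemble is collapsed to an effective free energy by
Boltzmann summation (log-sum-exp, overflow-safe);
ΔΔG‡ = G_R − G_S, so **positive ΔΔG‡ means the S product is favored**.
Conversions use er = e^(ΔΔG‡/RT), ee = 100·(er − 1)/(er + 1), and the
exact inverses; R = 8.314 J·mol⁻¹·K⁻¹, T defaults to 298.15 K.

Experimental records (unsigned ee + reported configuration) are
converted to signed ΔΔG‡ at the record's temperature; ee = 100% is
clamped to 99.9% (the conversion is singular at 100) with a warning.
Agreement is quantified by the mean unsigned error (MUE) and squared
Pearson correlation (R²). A record is *flagged* when the predicted and
experimental ΔΔG‡ disagree in sign **and** both |predicted ee| and
experimental ee are at least a confidence threshold (default 20%) —
confident predictions opposing confident measurements. Corrections
invert the reported configuration for flagged records (an involution);
reports carry pre- and post-correction statistics on the non-excluded
subset (records can carry exclusion tags for out-of-scope chemistry).

## 6. Synthetic verification fixtures (`tsforge.synthfix`)

All test data is generated, none stored. Sizes are the package's own
choice, selected so the full suite runs on one CPU in minutes.

* **Toy TS systems** are typed chains (4–20 heavy atoms) whose forming
  bond is terminal; all force-field parameters are drawn from seeded,
  physically plausible ranges, and the geometry is minimized to RMS
  gradient 10⁻⁶.
* **Mock-QM references** take the true-FF Hessian and negate the
  forming-bond mode's eigenvalue in place, recording the original
  eigenvalue as the per-structure replacement value ω. The eigenvalue
  replacement step then restores the true Hessian *exactly*, so the
  generating force field is the exact global optimum of the penalty —
  which is what makes parameter-recovery experiments well-posed
  (recovery to ~10 significant digits, penalty drops of ~10¹⁶).
* **The three-well system** is a deterministic butane-like chain whose
  single torsion (V₁ = 1.6, V₃ = 6.0) gives an anti global minimum and
  a degenerate gauche pair, each with ~120° basins — the search-
  completeness oracle is a 1° exhaustive scan whose stationary points
  are filtered to true minima via the lowest non-rigid Hessian
  eigenvalue (a start on the syn symmetry ridge relaxes onto a saddle
  and stalls there with zero gradient).
* **The chirality-null fixture** is a pair of exactly mirror-image
  templates with achiral chain fragments. Fragments are short (two
  rotatable bonds per assembly, nine wells) so that both mirror
  ensembles converge completely within a brief search; the predicted
  |ee| is then numerically zero (~10⁻¹² %), testing the entire
  assemble→search→Boltzmann→ee chain for spurious chirality.
* **Validation tables** draw true ΔΔG‡ uniformly in ±12 kJ·mol⁻¹, set
  predictions to truth + N(0, 2.0 kJ·mol⁻¹), and derive experimental
  ee/configuration from the truth — with the configuration *inverted*
  for the planted-misassignment ids. Planted cases are rejection-
  sampled to stay above the flagging confidence threshold and unplanted
  cases to stay below it, so the flagged set equals the planted set
  exactly by construction; the rejection step perturbs the error
  distribution by well under the 5% tolerance used in the half-normal
  MUE check.

## 7. Limitations

* The MM functional form covers stretches, bends, torsions, exp-6 vdW
  and fixed-charge Coulomb only — no cross terms, out-of-plane bends,
  stretch–torsion coupling or polarization.
* Hessians are finite-difference; analytic second derivatives would be
  faster for large systems.
* The assembly torsion scan optimizes one attachment dihedral per site;
  it relies on the subsequent conformational search for full relaxation.
* The synthetic generators make no attempt to mimic real
  quantum-chemical error structure; they exist so ground truth is known
  exactly. Reproducing published statistics for real catalyst systems
  requires the corresponding quantum-chemical reference data, which is
  outside the package's scope.
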