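# Methods

## Fuzzy comprehensive evaluation

Raw endpoint scores (dimensionless docking scores in the reference use
case) are mapped per endpoint to [0, 1] by the large-scale membership
function — min–max normalization over the compounds within one endpoint.
That is the only reading of the membership definition that reproduces the
published index column, and it makes the index affine-invariant per
endpoint: rescaling any endpoint's raw scores by αc + β (α > 0) changes
nothing. All bundled endpoints are treated as larger-is-better (a higher
docking score means stronger binding to the ADR target, hence a worse
expected reaction); an orientation flag per endpoint is exposed for reuse
with smaller-is-better quantities.

The aggregation operator is the weighted average M(·, +); max–min and
other fuzzy compositions are deliberately out of scope. Weights are
configuration, not derived: the 0.50/0.40/0.10 ADR weighting follows
reported incidence ranges that were never tabulated, so the package takes
any non-negative vector summing to 1 (tolerance 1e-9). Endpoint-to-weight
mapping for the bundled table is 3IP9 (GABA, convulsive) = 0.50, 3N8V
(COX, gastrointestinal) = 0.40, 2L0W (hERG, cardiac) = 0.10; the
single-factor comparison table pins this mapping, since its convulsive
baseline equals the 3IP9 template score. Degenerate endpoints (max = min)
raise rather than silently contributing a constant membership.

Display rounding is half-away-from-zero at 3 decimals, matching the
printed tables; comparisons in tests use |Δ| ≤ 5e-4.

## Interaction fields

* **Units.** Internal energies are kcal/mol. The steric truncation is
  exactly 30.0 kcal/mol; the conventional 125.4 kJ/mol figure is this
  default times 4.184, and conversion happens only at I/O boundaries.
* **Steric.** Lennard-Jones 6–12 with arithmetic radius combination
  (R = R_atom + R_probe) and geometric well depth. Probe: sp³ carbon,
  radius 1.70 Å, ε = 0.107 kcal/mol, charge +1 — the classical CoMFA
  default, since no probe is stated in the source setting.
* **Electrostatic.** Coulomb with distance-dependent dielectric ε(r) = r,
  giving a 1/r² energy, 332.0636 kcal·Å/(mol·e²) constant, magnitudes
  clipped at 30 kcal/mol. Lattice points whose steric energy sits at the
  truncation (buried inside a molecule) carry no meaningful
  electrostatics; they are flagged and imputed during descriptor assembly
  by the column mean over unburied molecules (the usual "mean" treatment;
  dropping the column is available by raising `min_sigma`).
* **Lattice.** Axis-aligned, isotropic spacing (default 2.0 Å), union
  bounding box of the aligned series plus a 4.0 Å margin, snapped outward
  to whole steps, at least 2 points per axis. These are standard CoMFA
  conventions; the original region settings are unpublished, which is
  exactly why model-statistic parity with the published table is not
  claimed (see "Limitations").
* **LJ parameters.** A small bundled per-element table (H, C, N, O, F, S,
  Cl, Br): Bondi van der Waals radii with generic OPLS/Tripos-magnitude
  well depths. Other elements error loudly rather than receive silent
  defaults.
* **Descriptor assembly.** Columns with sd < `min_sigma` (default 0.05
  kcal/mol, a mild filter suited to the synthetic series' scale) are
  dropped; each field block is then scaled to unit total variance so
  neither field dominates the regression a priori. The stored imputation
  means, column selection and block scales are re-applied verbatim when
  transforming new molecules (designed derivatives), never recomputed.
* Structure alignment is rigid-body least squares (Kabsch) on mapped
  framework atoms; force-field geometry optimization is intentionally not
  implemented — 3D coordinates are inputs.

## PLS and validation statistics

The latent-variable regression is NIPALS PLS1 on mean-centered, unscaled
data (scikit-learn's implementation behind this package's interface); at
full rank it coincides with ordinary least squares, which the tests check
against a normal-equations oracle.

Conventions, where the field is not unanimous:

* LOO q² = 1 − PRESS/SS_tot with SS_tot about each **training fold's
  mean**; a whole-set-mean variant is a flag. SEP = √(PRESS/(N − n − 1)).
* SEE and F use N − n − 1 residual degrees of freedom (n = latent
  components).
* Component cap defaults to 10; the selection policy is argmax q² with
  ties toward fewer components, and a parsimony policy (smallest n within
  a tolerance of the max) is available. Requested counts beyond
  min(rows − 1, columns, rank) are clipped with a recorded warning.
* External validation restores the squares in
  Q²_ext = 1 − Σ(yᵢ − ŷᵢ)²/Σ(yᵢ − ȳ_train)² — the unsquared form
  sometimes printed is not bounded by 1 and cannot be the intended
  statistic. r²_pred is the squared Pearson correlation of observed vs
  predicted test values, computed separately.
* Train/test splitting is seeded and uniform (default 22/7 of 29, ~3:1);
  the designated template molecule is guaranteed to appear in both roles
  by duplicating it into the test evaluation set.

**Progressive scrambling.** The response is perturbed along a ladder of
strengths t by the variance-preserving blend
y′ = μ + √(1 − t²)(y − μ) + t·perm(y − μ); t = 0 is the intact response
and t = 1 a full permutation. For each draw the model is re-cross-validated
and (r²_yy′, q², SDEP) recorded. cSDEP is the SDEP interpolated at the
reference correlation r²_yy′ = 0.85 (the common critical point); dq²/dr²yy′
is the fitted slope of q² against r²_yy′. The blend, rather than in-place
subset swapping, is used because it keeps the response variance constant
across the ladder; with subset swaps the q²-versus-correlation relation is
convex and a fitted slope overstates instability even for a perfectly
stable model. For a stable, essentially noiseless linear model at series
scale (N ≈ 30, small n) the slope sits near 1; it grows with overfitting
pressure (more components, smaller N), which is precisely what the
diagnostic is for. Everything is seeded; reps ≥ 10 are required.

Field contributions are Σ|coefficient|·(column sd) per block, normalized
to 100 %. Contour grids are (column sd)·(coefficient) mapped back to
lattice positions with filtered columns at 0 — invariant to uniform column
scaling, since the scale cancels in the product. Favored/disfavored levels
are the 0.80 quantile of the positive values and the 0.20 quantile of the
negative values, per field (the source does not say whether the fractions
apply jointly; per-field is chosen). One-signed grids yield a single level
with a warning.

## Derivative design and screening

Enumeration follows |P1| + |P5| + |P1|·|P5| over the two flagged ring
positions; with the standard 6 + 6 group sets this is the 48-derivative
library, ordered singles-then-doubles with the position-1 group varying
slowest, matching the published naming ("1-X-PAZ", "5-Y-PAZ",
"1-X-5-Y-PAZ"). Fragment geometries are idealized templates with standard
bond lengths oriented along the exit vector of the replaced atom; the
carbonyl and ethynyl caps' attachment chemistry is not drawn in the
source and is best-effort. No conformer search or synthetic-accessibility
scoring is attempted.

Screening-stage rules are pinned by the published survivor sets: stage 1
(genotoxicity) is inclusive (≥ 0 — a derivative exactly matching the
template's pLOEC is counted among the survivors), stage 2
(photodegradability) strictly positive (which correctly excludes the four
borderline derivatives), stage 3 (bioconcentration) strictly negative.
Relative changes are always recomputed from the stored template row. The
source quotes a photodegradability increase up to 15.87 % citing a
derivative that fails stage 1; this package reports ranges over actual
survivors and leaves the discrepancy documented rather than corrected.

Single-factor validation reports
relative_error = 100·|weighted − single|/|weighted| — the discrepancy
between the weight-attributed index change and the single-endpoint model's
change, as a fraction of the former. The weighted-change denominator is
the convention that reproduces the published comparison table; a
single-change denominator is available by flag. One printed cardiotoxicity
error (the first derivative's 15.07 %) follows from neither denominator
and is treated as a printing defect. The comparison baselines for the
gastrointestinal and cardiac endpoints in that table equal the respective
column maxima of the score table rather than the template's own row; the
bundled fixture transcribes the printed values verbatim.

## Risk and thermochemistry

ADD = C·IR·EF·ED/(BW·AT) — the standard EPA intake equation; the source
never prints its formula or parameter values, so scenario files are user
inputs and no published exposure table is an acceptance check. HI = ADD/RfD
is acceptable strictly below 1; RI = ADD·SF is negligible below 1e-6,
acceptable in [1e-6, 1e-4), unacceptable at or above 1e-4. Boundary
closures are unit-tested exactly as written. Thermochemistry records take
energies verbatim in the declared unit ("a.u." accepted as-is; the
published barrier magnitudes of ~40 under that label are chemically
implausible and deliberately not corrected), compute ΔG and ΔE by the sum
conventions, and rank pathways by ascending barrier.

## Synthetic congeneric series

The original 29 aligned 3D structures were never published, so the
structure-dependent pipeline is validated on a generated stand-in: a rigid
six-atom scaffold (identical and pre-aligned across the series) plus one
substituent atom at a fixed site whose van der Waals radius is drawn from
U(1.1, 2.2) Å and partial charge from U(−0.5, 0.5) e. True activity is
0.5·radius + 0.5·charge + N(0, sd²) with sd = 0.01 — an essentially
noiseless linear structure–activity relationship, so the field → PLS chain
is expected to recover it almost exactly (LOO q² > 0.5 and fitted r² > 0.9
by a wide margin), and failures indicate pipeline defects rather than
sampling noise. The generator is fully seeded; SDF round-trips preserve
charges and the non-tabular substituent radius via molecule-level
properties.

What the synthetic series does **not** emulate: conformational
flexibility, multiple interacting substituents, charge redistribution upon
substitution, alignment uncertainty, and activity nonlinearity. Passing
tests therefore demonstrate the correctness of the field algebra,
descriptor bookkeeping and PLS statistics — not predictive performance on
real congeneric series.

## Problem sizes and numerical choices

The default synthetic series (29 molecules, ~8×7×6 lattice, ≈ 330 retained
descriptors) keeps a full LOO validation under a second and the whole test
suite under a minute; scrambling tests subsample columns, which is valid
because every scrambling property used is scale-free. Ties in component
selection break toward fewer components; probe-on-atom coincidences receive
the truncation value; quantiles interpolate linearly between order
statistics; weights must sum to 1 within 1e-9.

## Limitations

* Published model statistics (q² = 0.560, r² = 0.999, …) are **not**
  reproducible from the published record: the 3D structures, lattice
  region, and the originating software's internals are unavailable.
  Model-quality properties on the synthetic series stand in for them.
* Docking scores, literature endpoint-model predictions (pLOEC, log t½,
  log K_ow), DFT energies and LC50-derived exposure concentrations are
  inputs, never computed here.
* The bundled fixture tables transcribe the published values including
  their internal inconsistencies, which are documented above rather than
  repaired.
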