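# Methods

## The endpoint and the models

log FM is the logarithm of the fetus-to-mother blood concentration ratio
at equilibrium. The package treats trans-placental passage as passive
diffusion and models log FM as a linear function of descriptors; it makes
no mechanistic (PBPK) or active-transport corrections.

Three fixed linear models are built in. `eq1` uses the binary Lipinski
rule-of-five flag, the heteroatom count with hydrogens included (nHet),
predicted Caco-2 permeability, the steady-state volume of distribution
(log L/kg) and the unbound plasma fraction Fu in percent. `eq2` (Takaku
form) uses MW, topological polar surface area and the maximum E-state
descriptor Hmax. `eq3` (modified Wang form, non-normalized variables)
uses the centred Moreau–Broto autocorrelation AATSC1c and the Z-modified
information content ZMIC1.

Fu enters `eq1` on the percent scale (0–100); a coefficient of 0.00526
is only meaningful there, so tables supplying fractions must be rescaled
by the caller. Caco-2 (and the other membrane permeabilities) are
consumed on whatever scale the supplying table uses — ADMETLab-style
exports print log cm/s — with no unit conversion attempted, because
fidelity to the source table is the only safe contract.

Classification uses the Di Filippo thresholds: values above −0.52 are
*crossing*, below −0.82 *non-crossing*, the closed band in between
*dubious*. The outer classes are defined by strict inequalities, so both
boundary values belong to the dubious band.

### What can and cannot be recomputed

The structure-derived block (MW, Vol, Dense, nHA, nHD, nRot, nRig, Flex,
nRing, MaxRing, nHet, Fsp3, TPSA, a Crippen logP estimate, the Ro5 flag)
is computed from SMILES/SDF. The ADMET block (caco2, MDCK, PAMPA,
logVDss, PPB, Fu, logS, logD) and the PaDEL block (Hmax, AATSC1c, ZMIC1)
are externally predicted quantities ingested from CSV and **cannot be
computed from structure** here. Consequently, per-compound reproduction
of published prediction sets is possible only when the original
externally predicted descriptor rows are supplied as a table; no such
table is bundled. All shipped validation is therefore property-based on
synthetic data with known ground truth.

## Descriptor conventions

* **nHet** — total atom count with hydrogens minus carbon count (water
  → 3, methane → 4).
* **Rotatable bonds** — single, non-ring bonds between two heavy atoms of
  heavy-degree ≥ 2, amide C–N excluded; nRig = heavy-atom bonds − nRot and
  Flex = nRot/nRig, reported as 0 when nRig = 0 so tiny molecules do not
  crash table processing.
* **Rings** — the symmetrized smallest set of smallest rings. Plain SSSR
  ring counts are atom-order dependent in symmetric cages (adamantane),
  which would break permutation invariance; the symmetrized set is
  deterministic. MaxRing is the atom count of its largest member, 0 for
  acyclic molecules.
* **Vol** — the fast bond/ring-corrected sum of Bondi sphere volumes
  (4/3·π·r³ summed over atoms, minus 5.92 Å³ per bond, 14.7 per aromatic
  and 3.8 per aliphatic ring). Absolute volumes from grid methods differ
  by a few percent; tests assert only the Dense = MW/Vol identity, not
  absolute values.
* **Ro5 flag** — strict by default (MW ≤ 500, logP ≤ 5, nHD ≤ 5,
  nHA ≤ 10, zero violations); `ro5_max_violations=1` switches to the
  common ≤ 1-violation variant. When a table supplies logP it wins over
  the structure-derived Crippen estimate.
* **Tables** — UTF-8 comma-separated CSV, "." decimals, case-insensitive
  header aliases from a versioned map (`logfm/data/aliases.json`). Blank
  numeric cells are flagged missing, never zeroed; model evaluation on a
  missing field raises an error naming it.

## Fitting and selection

OLS goes through statsmodels; the reported block is R², adjusted R²,
RMSE, PRESS, Q², F and its p-value. Conventions, chosen once and
configurable where stated:

* RMSE = sqrt(SSE/n). Dividing by n matches common QSAR reporting; a
  `rmse_dof="n-p"` switch gives the residual-degrees-of-freedom variant.
* PRESS via the hat-matrix identity Σ(eᵢ/(1−hᵢᵢ))², with leverages from
  an economical QR of the intercept-augmented design; Q² = 1 − PRESS/SStot.
  A leverage within 1e-10 of one raises an error (the point determines
  its own fit; its deleted residual is undefined). This happens in real
  designs — e.g. when exactly one training compound carries Lipinski = 0,
  that row is uniquely identified by the binary column — so `ols_fit`
  catches the condition and reports PRESS and Q² as NaN while keeping the
  otherwise-valid fit; the standalone PRESS routine raises. The identity
  is tested against an explicit refit-without-point-i loop at 1e-10
  relative tolerance.
* Amemiya's prediction criterion PC = SSE·(n+p)/(n·(n−p)) with p counting
  the intercept (a `count_intercept=False` switch drops it; the
  literature has both conventions). PC penalizes model size more harshly
  than adjusted R², which is why it drives subset selection.
* Best-subset search enumerates every subset in the configured size
  window (default 2–5 variables) when the candidate count fits the
  budget, otherwise falls back to greedy forward selection and flags the
  result as non-exhaustive. Ties in PC break by fewer variables, then
  lexicographic descriptor order, so results are deterministic.
* Train/test splitting is a pure function of (ids, n_train, seed).
* Held-out evaluation predicts without refitting. Test R² is computed
  about the test-set mean and reported unclamped (it can be negative);
  test R²_adj uses the test n together with the model's p; the test F is
  the implied overall F at those degrees of freedom.

## Atomic contributions

Fingerprints are folded Morgan/circular fingerprints (2048 bits, radius
2, chirality included) with the full bit→(center, radius) trace retained.
Pre-selection drops zero-variance bits and bits supported by fewer than
5% of compounds (configurable) — the most common hologram-QSAR practice.

The regression is NIPALS PLS (scikit-learn) on the unscaled 0/1 bit
columns, re-expressed in raw-bit form y = intercept + Σ wⱼ·bitⱼ. The
component count is chosen by an inner 5-fold cross-validated q² on a
seeded 75% training portion, capped at 10; held-out q² is reported on the
remaining 25%.

Attribution distributes each set bit's weight equally across its
environment occurrences and, within each environment, equally across the
atoms the environment covers; hydrogens are implicit and fold into their
heavy neighbor. A "center-atom-only" rule would concentrate weights but
discard the context atoms that made the environment distinct; equal
division is the neutral default. Conservation — atom contributions
summing to prediction minus intercept — holds by construction and is
asserted at 1e-9.

## Synthetic accessibility

The score combines a fragment-contribution term (mean database
log-frequency score of all radius-≤2 circular fragments, count-weighted,
with a −4 floor for fragments absent from the table) with complexity
penalties: size (nAtoms^1.005 − nAtoms), stereo (log10 of chiral-center
count + 1, unassigned centers included), ring complexity (log10 terms for
spiro and bridgehead atoms), a flat log10(2) macrocycle penalty for any
ring larger than 8 atoms, and a symmetry correction of
0.5·ln(nAtoms/nDistinctFragments) when fragments repeat. The raw value is
mapped from the empirical (−4, 2.5) range onto [1, 10] with logarithmic
compression above 8, then clamped. The published fragment-frequency table
and the published parameterization are used as-is (no re-tuning); the
table is loaded at runtime from the RDKit distribution's SA_Score
contribution data. Screening flags compounds scoring ≥ 6 (cut-off
configurable).

## Synthetic data: what it emulates and what it does not

`gen_reference_table` emulates a reference table of compounds with
experimental log FM. Marginals: Lipinski ~ Bernoulli(0.8) (most reference
drugs are drug-like), nHet ~ uniform integers 5–40 (small drug-like
molecules), caco2 ~ Normal(−5.0, 0.5) (log cm/s scale of ADMET exports),
logVDss ~ Normal(0.3, 0.6), Fu ~ Uniform(1, 95) percent. The response is
the `eq1` linear model plus Normal(0, 0.18) noise; 0.18 mirrors the
magnitude of the reference fit's training error so simulated 40/15
experiments are comparable to the reported statistics. Nuisance columns
with correlation 0.5 to the informative ones stress subset selection.

The generator samples independent marginals (plus the constructed
nuisance correlation); real descriptor tables have correlated descriptors
and non-Gaussian errors. Passing tests therefore demonstrate correctness
of the estimators and selection machinery under known truth — not
predictive validity on real chemistry.

`gen_fixture_molecules` provides (i) a 43-molecule functional-group panel
tagged by hydroxyl/carbonyl/nitro/halogen/polycyclic features, the
fragment classes with known transfer-promoting (carbonyl, hydroxyl,
nitro) or -restricting (halogen, rigid polycyclic) roles — the panel
response assigns +0.35/+0.35/+0.30/−0.45/−0.25 log units per tag plus
0.10 noise, and the attribution experiment recovers that sign pattern —
and (ii) matched 4-hydroxy vs 4-acetoxy N,N-dialkyltryptamine pairs
differing at exactly one substitution site, for paired-series designs.

## Problem sizes

The shipped experiments use 55-compound reference tables with 40/15
splits, 200 replicates for distributional checks, 50 random fixtures for
the PRESS oracle, 20 seeded replicates for attribution sign recovery and
a 57-molecule library for accessibility screening; the whole suite and
the acceptance script each run in well under a minute on one CPU.

## Known limitations

* No pKa/logD, no 3D conformers, no re-implementation of external ADMET
  predictors: the package consumes their outputs.
* The greedy fallback of the subset search is not guaranteed to find the
  PC optimum (the exhaustive path is, and is the default for ≤ 200 000
  candidates).
* Circular-fingerprint attribution is associative, not causal: an atom's
  weight reflects the bits it participates in, and collinear bits can
  shift weight between correlated substructures.
* The accessibility score ranks synthetic difficulty; it knows nothing of
  reagent availability or route legality.
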