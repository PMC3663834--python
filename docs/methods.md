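# Methods

## EEM charge model

Charges are the solution of the electronegativity-equalization system: for
every atom *i*, χ̄ = A_i + B_i q_i + κ Σ_{j≠i} q_j/R_ij, closed by charge
conservation Σ q_i = Q. The unknown vector is (q_1…q_N, χ̄); the matrix has
B_i on the atom diagonal, κ/R_ij off-diagonal, −1 in the χ̄ column and a row
of ones for conservation. Systems here are small (≤ ~100 atoms), so a dense
LAPACK solve is used; no iterative scheme, no cutoffs on 1/R terms.

Assumptions and conventions:

* **Units.** Distances are taken in ångström exactly as read from the SDF
  coordinates. Published parameter sets absorbed all unit conventions into
  their calibrated κ, A, B values, so the solver performs no conversion;
  a set must be used with the distance convention it was calibrated under.
* **Atom typing.** Parameters are keyed on (element, highest incident bond
  order). Aromatic bonds count as order 2 — source files may mark rings
  either with Kekulé orders or the aromatic flag, and both must resolve to
  the same parameters. A per-element wildcard entry acts as fallback after
  the exact bond-order match. Atoms with no matching entry raise
  immediately: published sets genuinely lack e.g. triple-bond C/N types,
  and silently substituting parameters would corrupt descriptors.
* **Degenerate geometry.** Coincident atoms (R_ij = 0) and singular systems
  raise typed errors rather than producing charges.

Two closed forms serve as independent oracles: the heteronuclear diatomic,
q₁ = (A₂−A₁)/(B₁+B₂−2κ/R), and the κ = 0 decoupled limit,
q_i = (χ̄−A_i)/B_i with χ̄ = (Q + Σ A_i/B_i)/(Σ 1/B_i). Because charges
depend on geometry only through interatomic distances, rigid motions leave
them invariant and atom permutations permute them; both are tested, along
with exact charge conservation (≤ 1e−10) and agreement with a brute-force
least-squares solve of the same system.

## Dissociation sites and descriptors

The phenol site is an oxygen bonded to exactly one hydrogen and one carbon
belonging to a six-membered all-carbon ring that is aromatic (all bonds
flagged, or orders alternating 1/2); fused systems qualify through any such
ring. The carboxyl site is a carbon single-bonded to a hydroxyl oxygen and
double-bonded to a second oxygen. Zero matches and multiple matches both
raise — polyprotic inputs are surfaced, not silently resolved — with an
explicit-site override for callers that know better.

The anion is constructed by deleting the acidic hydrogen *in place*:
surviving coordinates are bit-identical to the parent, the total charge
drops by one (the physically consistent choice for the EEM solve of the
anion), and the formal negative charge is recorded on the deprotonated
oxygen so the written SDF record round-trips. Descriptor extraction
verifies, atom by atom, that a supplied anion equals the regenerated one
before indexing charges through the H-removal mapping; mismatched pairs are
a consistency error rather than a wrong descriptor row.

## Regression models and statistics

Fitting is ordinary least squares (statsmodels) of experimental pKa on the
site-charge descriptors, with intercept. Conventions:

* R² is the squared Pearson correlation between predicted and experimental
  pKa. On training data this equals 1 − SSE/SST (asserted to 1e−10); on
  held-out folds the Pearson form is used as-is, which can exceed
  1 − SSE/SST when the test fold is small.
* RMSE = √(SSE/n); mean absolute error Δ̄ = (1/n)Σ|e_i|;
  s = √(SSE/(n−k−1)); F = (SSR/k)/(SSE/(n−k−1)) with
  SSR = Σ(ŷ_i − ȳ)². These are the classical residual-standard-error and
  overall-regression conventions; other conventions exist (notably for s
  and F on cross-validated subsets) and are deliberately not mixed in.
* Cook's distance D_i = e_i²/(m s²) · h_ii/(1−h_ii)², m = k+1. A
  leave-one-out refit oracle (n explicit refits) must agree to 1e−8.
  Outlier screening removes floor(0.1·n) molecules with the highest D_i
  (74 → 7 removed, 67 retained), ties broken by molecule id, and refits on
  the reduced set only. D_i itself is reported (not √D_i); the ranking is
  identical either way.
* Cross-validation stratifies by sorting molecules on pKa, cutting the
  ordered list into consecutive blocks of k (= fold count) and dealing each
  block's members randomly one per fold; the single partial block goes to a
  random subset of distinct folds, so fold sizes differ by at most one
  (74, k=5 → 15/15/15/15/14). All randomness flows through one explicit
  integer seed (numpy Generator); identical seeds give bit-identical
  reports. Degenerate folds (< 2 members) and rank-deficient or
  zero-variance designs raise typed errors.

## Synthetic data generator

Real curated structure series are not redistributable, so the generator
builds the study conditions from scratch:

* **Geometry.** A planar phenol template — hexagonal C6 ring with C–C
  1.39 Å and Kekulé-alternating orders, C–O 1.36 Å, O–H 0.96 Å placed on
  the C1–O axis so the unjittered template keeps an exact mirror plane, ring
  H at 1.08 Å, and one para pseudo-substituent atom at 1.40 Å — plus an
  acetic-acid-like template for the carboxyl path. Coordinates get uniform
  jitter ≤ 0.02 Å per component (seeded). Planarity is harmless: EEM
  consumes only distances.
* **Substituent effects.** The substituent's electron-withdrawing or
  -donating strength is modelled by shifting that element's A
  (electronegativity) parameter at solve time. Charges are affine in the
  EEM right-hand side, so every descriptor responds exactly affinely — and
  hence provably monotonically — to the shift; a geometric perturbation
  would make that only empirical.
* **Ground truth.** pKa = (known coefficients)·(actual EEM descriptors) +
  intercept + N(0, σ²) homoscedastic noise. The default study conditions
  are 74 molecules (the size of a typical curated phenol series), σ = 0.5
  pKa units, and generating coefficients (260, −90, 45, −70, 35) with
  intercept −77, chosen once so that with the reference parameter set
  (`gen_parameter_set(3)`) the noiseless pKa span is ≈ 0.4–10 with
  standard deviation ≈ 2.7 — the spread real substituted-phenol series
  show. Coefficient magnitudes in the hundreds are physical: site charges
  vary by only a few hundredths of an elementary charge across a series.
* **Random parameter sets.** A ∈ [2, 12], B ∈ [6, 16], κ ∈ [0.1, 1.0] for
  H, C, N, O at bond orders 1 and 2 — the ranges published calibrations
  fall into.

What passing on this data does *not* show: the generator has a single
substituent axis and exactly the linear descriptor→pKa mechanism the models
assume, so it validates the machinery (solver, site logic, statistics,
determinism), not the chemical adequacy of charge descriptors for arbitrary
real compound classes, tautomers, intramolecular H-bonding or multi-site
acids. Published parameter-set values are user-supplied from the original
calibration papers; the package ships the schema and registry loader, not
the numbers.

## Known limitations

* Single dissociation site per molecule; polyprotic inputs require an
  explicit site.
* No conformer generation and no geometry optimization anywhere; charges
  inherit whatever conformation the input SDF carries.
* V2000 SDF only; V3000 records are rejected.
* EEM only — no QEq/SQE variants, no charge models beyond the equalization
  system above, and no derivation of A/B/κ from QM charges.
* Acceptance-level verification runs on the synthetic series; problem
  sizes there (74 molecules, ≤ 40 for the leave-one-out oracle, 200 noise
  replicates) were chosen as the smallest that exercise every code path
  with stable statistics.
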