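# Methods

This package re-implements, as a tested library, the computational triage
used to find small-molecule hits for a cryptic secondary pocket on the
HSP70 nucleotide-binding domain: physicochemical pre-filtering of a
screening library, a two-stage consensus docking-score cascade, the
geometry of the pocket definition, post-processing of umbrella-sampling
data into a binding free energy, and steady-state SPR affinity fitting.
Everything runs on synthetic inputs with known ground truth; the docking
engine, the MD engine and all wet-lab steps are outside the package.

## Molecular-formula arithmetic (`chem_core`)

Formulas are element+count token strings ("C14H17N4OS"); parentheses,
hydrates and isotope labels are deliberately outside the grammar — every
formula this pipeline touches is a plain Hill string. Masses come from a
bundled table of IUPAC values: the monoisotopic mass of the most abundant
isotope per element (carbon exactly 12) and the 2021 standard atomic
weights. For an ion of charge z the mass of z electrons is subtracted
before dividing by |z|; the correction is ~0.5 mDa and is what makes the
calculated [M+H]+ of the primary fragment come out at 289.1118 rather
than 289.1123, matching high-resolution MS practice.

Ligand efficiency is LE = −RT ln(K_D)/HA in kcal·mol⁻¹ per heavy atom at
T = 298.15 K (R = 1.9872 × 10⁻³ kcal·mol⁻¹·K⁻¹), the conventional scale.
kcal↔kJ conversion uses the exact thermochemical factor 4.184.

## Known Drug Indexes (`kdi`)

Each of six descriptors (MW, logP, H-bond donors, H-bond acceptors,
rotatable bonds, PSA) is scored with a unit-amplitude Gaussian
I_d = exp(−(x−μ_d)²/2σ_d²) centred on the distribution of drugs in
clinical use. KDI_2a = Σ I_d (maximum 6) rewards compounds that are
decent on all axes; KDI_2b = Π I_d (maximum 1) punishes any single bad
axis much harder. The published campaign retained compounds with
KDI_2a ≥ 5.66 and KDI_2b ≥ 0.70.

Calibration uses sample moments (mean, n−1 standard deviation) of a
reference table rather than a histogram least-squares fit: for Gaussian
data the two coincide, and moments need no binning choices. The original
reference parameters are not distributed, so the package always
calibrates from a user-supplied (or synthetic) reference set. Threshold
combination defaults to logical AND (`mode="both"`), configurable to OR
or single-index modes; retention is score ≥ threshold, the only reading
under which thresholds above the known-drug averages shrink a library.

## Consensus docking cascade (`triage`)

Score tables (GS, CS, ChemPLP, ASP, HB per compound per stage) are
inputs. A compound survives a stage iff all five scores are ≥ that
stage's minima; any one low score eliminates, and each eliminated
compound's report lists every criterion it failed. Defaults are the
published stage-1 minima (CS 25, GS 70, ChemPLP 70, ASP 27, HB 0.2) and
stage-2 minima (CS 30, GS 75, ChemPLP 80, ASP 33, HB 1.0); boundary
scores survive because elimination is defined on strict "<". The
stage-2 table must be a subset of stage-1 survivors (the second docking
pass is only run on survivors); a stray id is an error, not a warning.
The structural-alert filter is SMARTS substructure matching via RDKit
and ships with an empty default pattern list, since the alert list used
in the campaign is not distributed.

## Pocket geometry (`structsite`)

PDB/mmCIF files are read with gemmi into a flat atom list, model 1 only;
altloc groups keep the highest-occupancy conformer (ties by altloc id).
The pocket is a sphere — centre at a named anchor atom (in the campaign,
the ligand's thiazole nitrogen), default radius 10 Å — and a residue
lines the pocket iff any of its atoms lies within the radius, the
convention docking cavity definitions use (a centroid rule would drop
long side chains that reach into the site). Distances are Euclidean in
the deposited frame with an exact 10 Å = 1 nm conversion; no
superposition or symmetry expansion is applied. Deposited structures
are not bundled; tests run on synthetic fixtures written by
`synth.gen_toy_structure`, whose coordinates are exact by construction.

## Umbrella-sampling analysis (`md_analysis`)

The module consumes per-window reaction-coordinate samples (the pulling
and umbrella simulations themselves are not run here) and estimates the
potential of mean force by self-consistent WHAM:

    p_j = (Σ_i n_ij) / (Σ_i N_i exp[(f_i − w_i(x_j))/kT])
    f_i = −kT ln Σ_j p_j exp[−w_i(x_j)/kT]

with harmonic biases w_i(x) = k(x−x0_i)²/2. Iteration starts from all
offsets zero, pins f_1 = 0 as the gauge, works in log space
(`scipy.special.logsumexp`) for stability, and stops when the largest
offset change is below 10⁻⁶ kJ/mol (cap 10⁵ iterations; non-convergence
raises). Default grid: 200 bins over the pooled sample range; a bin is
occupied at ≥ 1 sample; unoccupied bins are NaN, never interpolated.
Adjacent windows without histogram overlap trigger a warning (or an
error, per `on_no_overlap`). With a single unbiased window the estimator
reduces exactly to −kT ln(histogram).

The binding free energy is ΔG = min(PMF over the bound interval) −
mean(PMF over the dissociated plateau interval), negative favourable —
the sign convention of the reported −11.2 kcal/mol. The kcal/kJ pair
printed for that value is inconsistent at one decimal under ×4.184, so
neither number is used as a conversion oracle anywhere in the tests.

Hydrogen bonds are counted geometrically: donor–acceptor distance
≤ 0.35 nm and hydrogen–donor–acceptor angle (vertex at the donor heavy
atom, the convention of the MD tool those cutoffs come from) ≤ 30°, each
(donor, acceptor) pair at most once. Users who prefer the
donor–hydrogen–acceptor convention can wrap the frame accordingly; the
criterion is deliberately a pure function of coordinates.

## Steady-state SPR fitting (`spr_fit`)

Equilibrium responses follow the 1:1 Langmuir isotherm
R(c) = R_max·c/(K_D + c). Fitting is nonlinear least squares in
log-parameter space (guaranteeing positivity) with deterministic
initialization: R_max₀ = 1.1 × max observed response, K_D₀ = the tested
concentration nearest half of that — robust for both saturating and
weak binders. Inputs are assumed DMSO-corrected and
reference-subtracted, as the instrument software leaves them.

Non-saturation — the behaviour that makes a K_D unreliable and often
signals weak or nonspecific binding — is operationalized as: fitted
K_D ≥ 2 × the highest tested concentration (boundary flagged), OR the
largest observed response < 50% of the fitted R_max. Both ratios are
reported as diagnostics and the thresholds are configurable.
`stoichiometric_rmax` gives the theoretical ceiling
immobilized RU × (analyte MW / immobilized-protein MW) × stoichiometry.

## Synthetic data (`synth`)

Generators are pure functions of (seed, arguments); each derives its own
stream from the seed plus a CRC32 of the generator name, so outputs are
byte-stable as generators are added. What they emulate:

- **Reference descriptors**: six independent Gaussians at oral-drug-like
  moments (MW 350 ± 100 Da, logP 2.5 ± 1.5, HD 2 ± 1.5, HA 5 ± 2.5,
  RB 5 ± 3, PSA 80 ± 30 Å²); count-like columns are clipped at zero.
- **Screening library**: a druglike/non-druglike descriptor mixture and
  five docking scores driven by a latent per-compound affinity through a
  linear-Gaussian model with configurable pairwise correlation ρ
  (z_f = √ρ·latent + √(1−ρ)·ε_f); stage-2 scores add independent noise.
  Latent truth is emitted for recovery tests.
- **Umbrella windows**: samples drawn from the *exact* biased Boltzmann
  density ∝ exp(−[U(x)+k(x−x0)²/2]/kT) by inverse-CDF on a 2¹⁴-point
  grid with linear interpolation — no Markov chain, hence no
  equilibration or autocorrelation artefacts. The default test scenario
  uses 17 windows, k = 700 kJ·mol⁻¹·nm⁻², 5000 samples per window at
  298 K, the scale of the reported umbrella protocol.
- **SPR curves**: Langmuir responses with multiplicative Gaussian noise
  on an eight-point series spanning 6.25–500 µM (two-fold steps, top
  point capped at 500 µM so the series matches the reported range).
- **Toy structures**: standard-conforming PDB text with exactly
  specified coordinates, for geometry and parsing tests.

What the synthetic data does **not** emulate: real descriptor
correlations (logP and PSA are anticorrelated in real libraries),
docking-score non-Gaussianity, conformational sampling autocorrelation,
and SPR drift/solvent artefacts. Passing tests therefore demonstrate the
*estimators and filters* are correct, not that the original screening
counts would be reproduced on the commercial library.

## Problem sizes and numerical choices

Test and acceptance runs use 10³–10⁴-compound synthetic libraries,
17 × 5000 umbrella samples and 100–200 SPR noise replicates — sizes
chosen to make sampling error a small fraction of each test's tolerance
while keeping the whole suite fast. WHAM tolerance 10⁻⁶ kJ/mol; SPR
optimizer tolerances 10⁻¹⁴; KDI identities asserted to 10⁻¹²;
"well-sampled" PMF bins for recovery comparisons are those with > 200
samples. PMF comparisons align the arbitrary additive constant by the
mean offset before computing RMS.

## Known limitations

- The headline screening counts (50,004 → 10,823 → 1,173 → 166 → 24 → 5)
  depend on a commercial library and docking engine and are not
  reproducible here; the package reproduces the *rules*, verified
  against brute-force oracles.
- WHAM error bars (bootstrap) are not implemented.
- Kinetic (on/off-rate) SPR fitting is out of scope; only equilibrium
  responses are modelled.
- The formula grammar excludes parentheses and isotope labels by design.
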