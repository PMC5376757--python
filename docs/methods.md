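# Methods

This note documents the models implemented in `trekleak`, the defaults they
ship with, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Electrodiffusion model (`ionic_driving`)

The channel is a two-cation constant-field (GHK) pore. K⁺ carries the
reference permeability `p_k`; Na⁺ carries `alpha·p_k` with
α = P_Na/P_K ≥ 0; NMDG⁺-like substitutes are strictly impermeant. The
bi-ionic reversal is

E_rev = (RT/F)·ln((K_o + α·Na_o)/(K_i + α·Na_i)),

which reduces exactly to the K⁺ Nernst potential at α = 0. Per-species flux
uses the GHK current equation in arbitrary units (permeability × mM); the
removable singularity at V = 0 is replaced by its analytic limit
p·(c_in − c_out). Sign conventions: V is inside minus outside, outward
current positive.

Defaults, with reasons:

- **Temperature 294.15 K** — recordings at room temperature (21–22 °C);
  RT/F = 25.35 mV.
- **Bath**: ND96, 2 mM K⁺ / 96 mM Na⁺; substitution series exchange Na⁺ (or
  NMDG⁺) for K⁺ at a fixed 98 mM total monovalent cation.
- **Oocyte cytosol 108 mM K⁺ / 10 mM Na⁺** — standard *Xenopus* values; the
  two-point decade slope is provably independent of this choice (the internal
  term cancels), and the tests assert that invariance.
- Divalents and Cl⁻ are outside the channel model; any non-selective
  background is a separate ohmic leak in the oocyte model. This keeps the
  selectivity engine bi-ionic and analytically invertible.

**Decade slope.** `decade_slope` is an unweighted OLS of E_rev on
log₁₀[K⁺]ₒ. With a sodium leak the relation is convex, so the slope depends
on the K⁺ range: the headline sub-Nernstian value (≈13 mV/decade at α = 0.2)
refers to the low-K decade, and the package adopts the 2 → 20 mM two-point
convention for that comparison. This convention is a documented choice, not
a claim about the original analysis procedure.

**Permeability-ratio fit.** One-parameter least squares of measured E_rev
against the GHK prediction, α constrained ≥ 0 (lmfit/Levenberg–Marquardt);
95% CI from the Jacobian standard error. Noiseless generate-then-fit is an
identity to ≤ 1e-6 relative error (tested).

## Stretch gating (`channel_gating`)

Peak activation is a Boltzmann of pipette pressure,
P_open = 1/(1 + exp((P − P½)/k)), so stronger suction (more negative P)
opens more channels; activation is treated as instantaneous because only
desensitization is analyzed. Within a step the normalized current is

I(t) = P_open(P) · (f_f·e^(−t/τ_f) + f_s·e^(−t/τ_s) + f_p),  f_f+f_s+f_p = 1,

normalized to a fixed pH_i 5.0 reference peak (a constant, not a mechanistic
proton-gating model).

Kinetic defaults are the published time constants (WT τ_fast 68 ms,
τ_slow 1.4 s; mutant 1.0 s and 2.5 s). The amplitude split (WT
0.55/0.35/0.10; mutant 0.25/0.45/0.30) and the pressure sensitivities (WT
P½ = −35 mm H₂O, mutant −15 mm H₂O, k = 8) are free defaults with no
ground-truth status — the figures they emulate are not tabulated — chosen to
respect the reported directions (reduced fast component, larger persistent
current, mechano-hypersensitivity).

**Bi-exponential fit.** Nonlinear least squares of
A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s) + A_p with a free additive constant
(whether the original fits fixed the persistent term is unknown).
Initialization: τ guesses from the times to 63% and 90% of the observed
decay; bounds τ ∈ [1 ms, 60 s]; amplitudes ≥ 0. After the fit the
exponentials are ordered (τ_slow ≥ τ_fast) and amplitudes renormalized to
fractions. Fits with τ_slow/τ_fast < 2 are flagged
`single_exponential_like` instead of being silently returned; traces shorter
than 3·τ_slow are flagged `short_trace`. The generator warns when the sample
rate gives fewer than 5 samples per τ_fast.

Synthetic stretch records are sampled at 1 kHz for 6 s (WT) / 10 s (mutant)
— at least ~4 slow time constants, which is what makes the slow-τ estimate
stable — with additive Gaussian noise of 1% of the step's peak.

## Pharmacology (`pharmacology`)

Activation: fold(c) = 1 + (F_max − 1)·cʰ/(cʰ + EC₅₀ʰ); inhibition:
remaining(c) = 1/(1 + (c/IC₅₀)ʰ). Published parameters: BL-1249 EC₅₀
12.8 μM (WT) / 15.2 μM (mutant), maximal fold 35 / 42.4; arachidonic acid
EC₅₀ 6.9 / 3.6 μM (its maximal fold is unprinted; default 10). Hill
coefficients are never printed, so h defaults to 1 everywhere. Blocker IC₅₀
defaults (fluoxetine 80 μM, verapamil 62 μM, mutant ×3 for the reported
reduced block sensitivity) are likewise free defaults.

**Fitting.** Weighted (√n per row) nonlinear least squares. Residuals are
taken on the log scale by default because the synthetic scatter — like
fold-change scatter between oocytes — is multiplicative (constant CV); this
also stops the top of a 35–42-fold curve from dominating the objective. The
Hill coefficient stays fixed at 1 unless `vary_h=True`: five log-spaced
concentrations cannot usefully constrain a third shape parameter, and
freeing it roughly triples the EC₅₀ sampling error at these designs. Flags:
EC₅₀ more than 10× outside the tested range, and F_max extrapolation
(occupancy at the top concentration < 90%).

Synthetic tables use the log-spaced grids around the EC₅₀ ({1, 3, 10, 30,
100} μM for BL-1249; 11 points over 0.3–30 μM for AA), 5% multiplicative
noise per replicate, and the published replicate counts (WT n = 3,
mutant n = 8; AA n = 7/8) averaged per concentration.

**Selectivity rescue.** α_eff = α·(1 − occupancy) with occupancy the Hill
fraction of the activator — a minimal phenomenological stand-in for the
activator stabilizing the selectivity filter. At saturating drug α_eff → 0
and the decade slope returns to Nernstian; the rule never produces
α_eff < 0 or > α (property-tested).

## Virtual TEVC (`oocyte_tevc`)

Total membrane current is a sum of GHK channel populations (each with its
own permeability profile, expression scale and per-limb modulation), a
phenomenological inward rectifier, and an ohmic leak:

- **Kir2.1**: I = g·(V − E_K)/(1 + exp((V − E_K − 10 mV)/6 mV)) — a steep
  rectifier whose only required role is anchoring the resting potential near
  E_K.
- **Endogenous leak**: ohmic, default reversal −20 mV, used to emulate
  leaky-cell behavior (e.g. sub-Nernstian WT slopes); off by default.

Protocols: the standard ramp (−120 → +40 mV in 3.5 s from −80 mV holding)
and step family (−130 → +50 mV, 10-mV, 200-ms). Currents are quasi-static —
no capacitance, series resistance, or space-clamp artifacts — and the
absolute scale is a free "expression level" (nominal μA). An optional
first-order activation relaxation (default τ 100 ms) reproduces the slow-
activation "hook" on steps to very negative potentials; it is off by default
and steady-state IVs are the primary product.

`measure_erev` interpolates the IV zero crossing linearly (most negative
crossing with a warning if noise creates several); `solve_em` sign-scans
total current at 1-mV resolution over [−150, +50] mV, requires a unique
bracket, and refines it with Brent's method to 1e-3 mV. E_m is invariant
under overall conductance rescaling (tested), and adding a Na⁺-permeable
population can only depolarize, never push E_m below E_K (tested).

**Heterodimers.** K₂P channels are dimers; co-injected WT : mutant cRNA at
fraction f assembles binomially (f², 2f(1−f), (1−f)²). Any dimer containing
a mutant subunit takes α_het = 0.2 by default (mutant-dominant), because
co-expressing cells remain Na⁺-permeable and depolarized; configurable.

**β₁-adrenergic modulation** is a per-genotype pair of (outward, inward)
limb scales: WT (0.1, 0.1) — near-complete suppression — and
mutant-containing (1.0, 1.3) — persistent outward current with an enhanced
inward leak. These are directional defaults with no ground-truth status.

**Fixture suite.** `generate_fixture_suite` writes TSV/CSV datasets for the
selectivity series (n = 10 replicate-averaged E_rev per point, 1 mV/cell
noise), the dose–response tables, the stretch traces, and co-expression IVs,
plus `manifest.json` recording the root seed, every derived per-file seed
(CRC-keyed SeedSequence spawns, stable across processes), and every
generating parameter. Same config + seed ⇒ byte-identical files (tested).

## Ventricular AP (`tp06`, `ventricular_ap`)

The base is the ten Tusscher–Panfilov (2006) human ventricular epicardial
model, transcribed in full (19 states) into `tp06.py`. It is a stand-in for
"a computational model of the human ventricular action potential": the claim
under test is the direction of effect of an added current, not
model-specific numbers.

The added background K₂P current is
I_K2P = p_k2p·[Φ_GHK(K⁺) + α·Φ_GHK(Na⁺)] (pA/pF), its K⁺ and Na⁺ limbs
feeding the respective intracellular ion balances; intracellular Na⁺/K⁺
inside the GHK terms are the model's dynamic state variables.

- **p_k2p calibration**: chosen so the α = 0 current at +20 mV equals 5% of
  I_K1 at −90 mV at baseline concentrations — an explicit convention for a
  "mild" leak (`default_p_k2p()`, ≈7.6e-4), configurable.
- **Integration**: Rush–Larsen exponential steps for the 12 gates, forward
  Euler for V, concentrations and the RyR variable — the customary scheme
  for this model family — at a fixed 0.01 ms step (numba-compiled). Halving
  the step changes every biomarker by < 1% (tested). V is recorded every
  0.01 ms so the finite-difference dV/dt_max is grid-converged.
- **Pacing**: 1 Hz, −52 pA/pF × 1 ms stimulus, 50 beats to quasi-steady
  state by default. The test suite uses 4–8-beat trains for the directional
  and monotonicity properties, which are insensitive to the remaining slow
  drift; the packaged regression fixture
  (`data/tp06_epi_reference.json`: RMP −85.59 mV, dV/dt_max 394.2 mV/ms,
  APD₉₀ 308.2 ms) was computed once at the full default pacing and is
  re-verified at that pacing.
- **Biomarkers**: RMP = minimum diastolic V; dV/dt_max by centered finite
  difference; APD₅₀/APD₉₀ from the time of dV/dt_max to 50%/90%
  repolarization of (peak − RMP), crossings interpolated. Traces without an
  upstroke (dV/dt_max < 1 mV/ms) raise an error. The final two beats are
  compared and >1% APD₉₀ discrepancy sets an alternans flag.

With the calibrated leak, moving α from 0 to 0.2 depolarizes the resting
potential by ≈ +0.34 mV and lowers dV/dt_max by ≈1.5%; both effects are
strictly monotone over α ∈ [0, 0.5] (tested). A selective leak (α = 0)
instead hyperpolarizes slightly and shortens APD — the expected behavior of
adding a pure K⁺ conductance. Spontaneously beating (HL-1-like) cells are
not modelled; the paced ventricular cell covers the depolarization and
upstroke claims.

## Orchestration (`reporting`, `cli`)

`run_pipeline` executes config-selected scenarios end to end and writes
fixtures, a results table, a JSON manifest, a JSON-lines log (stage, seed,
wall time), and a markdown summary. Comparison tolerances: ±2% relative for
deterministic quantities; for stochastic generate-then-fit recoveries ±15%
or the published ±SEM, whichever is wider; directional claims as one-sided
bounds. The AP scenario uses a 20-beat train plus one full-pacing regression
run. A `--negative-control` mode deliberately mislabels α = 0 data as the
mutant fixture; the selectivity rows must then fail and the CLI exits
nonzero — a self-test that the comparison machinery can reject wrong data.

## What the synthetic data do and do not show

The generators draw from the same model families the fitters assume
(GHK reversal + Gaussian E_rev noise; exact bi-exponential decay + white
noise; exact Hill curves + multiplicative noise). Passing tests therefore
demonstrate correctness of the forward models, the estimators, and their
calibration under realistic noise magnitudes and replicate counts — not
robustness to model misspecification in real recordings (endogenous
conductances, drift, rundown, activation kinetics overlapping
desensitization, correlated errors). The single deliberate misspecification
exercised is the mono-exponential trace, which the desensitization fitter
must flag rather than report. Real-data caveats of the oocyte and AP models
are listed in their sections above.

## Known limitations

- Bi-ionic GHK cannot represent multi-ion pore effects (anomalous mole
  fraction, Eyring barriers) — out of scope by design.
- The pressure–response functional form (Boltzmann) and all unprinted
  amplitude/pressure/blocker defaults are conventions, not measurements.
- The AP base model is a generic epicardial cell, not the (unidentified)
  model of the original appendix, and HL-1 pacemaking is not represented;
  quantitative RMP/upstroke shifts are therefore package-specific, and only
  their signs and monotonicity are asserted.
- Extracellular-pH modulation, TREK-2/TWIK-1 heteromers, MD simulations and
  variant prioritization are out of scope.
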