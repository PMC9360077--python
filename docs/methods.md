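# Methods

## Scope and intent

`nanopbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model for nanobiomaterials (NBMs) given intravenously to rats, together
with the statistical machinery used to parametrize and interrogate it:
a Bayesian posterior over six kinetic parameters sampled with a robust
adaptive Metropolis (RAM) chain, average-absolute-fold-error (AAFE) model
evaluation, and local sensitivity analysis of blood exposure. The in vivo
measurements that motivated this design (two dose groups of
cabazitaxel-loaded PACA nanoparticles; three dose groups of the IR780-loaded
lipid carrier LipImage™ 815) are not publicly deposited, so the package ships
a synthetic-data generator that reproduces the published study *layout* and
noise structure; every statistical claim made by the test suite is therefore
a statement about parameter recovery under the model's own assumptions, not a
reproduction of in vivo estimates.

## The compartmental model

Amounts (µg) are tracked in 14 main compartments — arterial blood, venous
blood, upper airways, tracheobronchial region, pulmonary region, liver,
spleen, kidney, heart, brain, GI tract, remaining tissue ("rest"), lymph
nodes and GI lumen — in 8 phagocytizing-cell (PC) sub-compartments
(pulmonary, liver, spleen, kidney, heart, brain, GI tract, rest), and in
three irreversible sinks (urine, feces, hepatic metabolism). Four clearance
routes operate: renal (kidney tissue → urine, first-order at the estimated
k_kidneyEl), hepatic metabolism and the biliary→fecal path (fixed
first-order rates), and lymphatic drainage (tissue → lymph nodes, with slow
lymph-node → venous return); lymph-node retention is the fourth route's
reservoir rather than a sink. The IV bolus deposits the full dose
(dose-per-body-weight × body weight) in arterial blood at t = 0.

Circulation is anatomical: the nine systemic organs draw from the arterial
pool in parallel (their flows sum to the cardiac output) and return to the
venous pool; the pulmonary region sits in series, receiving the entire
cardiac output from venous blood and returning to arterial.

### Blood–tissue exchange

Each perfused organ exchanges with its inflowing blood through a
permeability–flow product χ·Q (χ dimensionless, Q the regional flow in
mL/h). The capillary is not tracked as a state; eliminating its
concentration at quasi-steady state (well-mixed capillary) gives an
extraction fraction

    E = χ / (1 + χ),

so the organ receives E·Q·C_in, returns E·Q·C_tissue/P (P the shared
tissue–blood partition coefficient), and (1−E)·Q·C_in passes through to the
downstream pool. This reduces to delivery at rate χ·Q for χ ≪ 1 and to
flow-limited exchange for χ → ∞. The saturating form matters: the published
estimation bounds allow χ up to 150, and a naive bypass scheme with a
literal (1−χ) pass-through term has circulation loop gain ≈ (χ−1)² and is
exponentially unstable there (we verified the blow-up numerically). With E
∈ [0, 1) the rate matrix is Metzler with zero column sums, which guarantees
non-negativity, dynamic stability, and exact mass conservation for every
admissible parameter vector — properties the test suite asserts across the
full bounds box. The estimated χ_rich is applied to the richly perfused
organs (pulmonary, liver, spleen, kidney, heart, GI tract); brain (default
χ = 1e-3, encoding the blood–brain barrier), airways (1e-2) and rest (0.1)
use fixed, configurable permeabilities.

### Phagocytizing cells

Each PC sub-compartment fills from its host tissue at
k_up = k_base · max(0, 1 − A_pc/capacity) and releases at k_de, with
k_base = k_sab0 in the spleen and k_ab0 elsewhere. Capacities default to
unbounded (linear uptake), making the whole system linear time-invariant;
a finite capacity switches on the clamp and only then makes the model
nonlinear.

### Numerical integration

`simulate` integrates the 25-state system with LSODA (default rtol 1e-8,
atol 1e-10), supplying the constant analytic Jacobian in the linear case.
The renal rate may reach 900 h⁻¹ against organ time constants of hundreds of
hours, so a stiff-capable method is required. Total mass is checked against
the dose at every output time (tolerance 1e-6 relative); solver undershoots
below zero larger than 1e-9 of the dose raise an error, smaller ones are
floored to zero in observables. Observables pool tissue + PC amounts over
organ mass (µg/g, tissue density fixed at 1 g/mL); "blood" pools arterial +
venous over blood volume; "lung" maps to the pulmonary compartment.
Trajectories contain no residual capillary blood contribution.

## Physiology and fixed kinetics

The source publication prints no physiological constants, so the package
ships standard adult-rat reference values (Brown et al. 1997 compilation):
organ masses and blood volume as fractions of a default 250 g body weight,
regional flows as fractions of a cardiac output of ≈83 mL/min (250 g),
everything scaling linearly with body weight. The "rest" mass and flow are
defined as remainders, which enforces exact mass and flow closure by
construction. The non-estimated kinetic rates (lymphatic, biliary, fecal,
hepatic-metabolism, lymph-node return) originate in the lineage model this
structure descends from; their influence on the outcome is small, and they
are shipped as clearly labelled placeholder defaults of 1e-3 h⁻¹, all
overridable through the YAML configuration (section `fixed_kinetics`).

## Likelihood, prior, posterior

For a dataset D of N records (organ, time, animal, concentration), one
forward simulation per θ at the union of the design's measurement times
yields predictions matched to records by exact (organ, time) lookup — no
interpolation. The data likelihood is

    ln P(D|θ) = −(1/N) · Σ_i [ln(predicted_i / observed_i)]²,

the squared-log-ratio form whose conjugate error model is i.i.d.
multiplicative log-normal noise. Predictions are clamped below at 1e-12
µg/g; solver failures map to −∞. Note the deliberate unit split: the
likelihood uses natural logs, AAFE (below) uses log10 — both exactly as the
method defines them.

The prior is Jeffreys' scale form, p(θ_j) ∝ 1/θ_j, truncated to the
published per-parameter boxes (constructed in the source as a factor 30
either side of manually pre-optimized values; the boxes themselves are
shipped as data, the pre-optimization is not re-enacted). All six parameters
are positive rates or coefficients, for which the 1/θ form — uniform in
log-space — is the standard uninformed choice and matches the
factor-symmetric construction of the bounds. The posterior is the
unnormalized product; the evidence integral is never computed because the
sampler needs only density ratios.

An important practical consequence of the 1/N in the exponent: the
likelihood is *tempered*. Its total information content does not grow with
the number of records, so posteriors are intentionally broad (the source
reports some parameters spanning two orders of magnitude) and posterior
medians of weakly identified parameters shrink toward the geometric center
of their prior box. See "Known limitations".

## Sampling

The RAM sampler operates in z = ln θ, where the truncated Jeffreys prior is
exactly uniform — the 1/θ density and the exp-transform Jacobian cancel — so
the in-bounds target is just the data log-likelihood. Proposals are
z' = z + S·u with u standard normal and S lower-triangular; after every
iteration S is updated so that SSᵀ tracks a shape with stationary acceptance
α* via

    S' S'ᵀ = S (I + η_n (α_n − α*) u uᵀ/‖u‖²) Sᵀ,  η_n = min(1, d·n^(−γ)).

Defaults (α* = 0.234, γ = 2/3, 1e5 iterations, 50% burn-in, start at the
geometric midpoint of the box, initial scale 0.1 of each log-range) follow
the sampler family's standard recommendations; the source states none of
its settings. Out-of-bounds proposals are rejected without simulating but
still drive adaptation, which stops the proposal from inflating against the
box walls. Everything is deterministic given the seed. Setting the
adaptation off (η ≡ 0) recovers plain Metropolis, which the tests use for a
stationarity check against known Gaussian bin probabilities.

`run_fit` optionally refines the best sampled point with a bounded
Nelder–Mead maximization of the in-box log-likelihood ("MAP polish"). On
noise-free synthetic data this refinement recovers the generating parameters
to machine precision (residual mean squared log error < 1e-12), which is the
package's structural-identifiability check.

Posterior summaries report the median, the equal-tailed 90% credible
interval (5th–95th percentiles — the source defines the interval only by its
90% content; a highest-density variant sits behind a flag), Pearson
correlations over draws, and kernel densities estimated in log-space on a
grid spanning the bounds, renormalized to unit trapezoid integral over the
box.

## Model evaluation (AAFE)

    AAFE = 10^[(1/N) Σ |log10(predicted_i/observed_i)|]

is computed overall and per organ at any θ (conventionally the posterior
median). It is 1 exactly at a perfect fit, symmetric in
prediction/observation, and invariant to common rescaling. For the
generator's log-normal noise with log-scale sd σ the large-N AAFE tends to
exp(σ·√(2/π)) (folded-normal mean; ≈1.271 at σ = 0.3), which the tests
verify.

## Local sensitivity

Sensitivity of blood exposure is the elasticity S = (ΔAUC/AUC)/(Δp/p), with
AUC the trapezoidal integral of arterial+venous *amounts* (µg·h) on a
geometric time grid over a 336 h default horizon, and Δp = 0.10·p one at a
time, upward (a central-difference variant is available). The source's text
sets the change at 10% of the original value and then writes "Δp/p = 1.1";
1.1 is the multiplier p → 1.1p, not a relative change, and the elasticity
formula requires the relative change, so this package uses Δp/p = 0.10.
In the linear (unbounded-capacity) regime the dose elasticity is exactly 1,
and for a pure first-order elimination reduction AUC(∞) = dose/k gives the
closed form S = ((1/1.1)−1)/0.1 ≈ −0.9091 — both serve as oracles in the
tests. `oat_scan` ranks |S| and classifies parameters below a configurable
threshold (default 0.1) as low-influence.

## Synthetic data generator

`builtin_designs()` encodes the five published dose groups: PACA-Cbz at 0.5
and 3.5 µg/g bw with blood punctures at 1, 3, 7, 15, 30 min, 1, 4 h, 1, 2,
4, 14 d; LipImage™ 815 at 0.046, 0.15 and 0.46 µg/g bw with punctures at
15, 30 min, 1, 4, 24 h; all with sacrifice at 1 h, 1, 2, 4 and 14 d, four
animals per time point, and organ panels {blood, liver, spleen, lung,
kidney, heart, brain}. The generator simulates the model at a "true" θ
(defaulting to the published posterior medians per dose group, shipped as
fixtures) and draws each record as prediction × exp(ε), ε ~ N(0, σ²)
i.i.d., with σ = 0.3 by default — the error form conjugate to the
likelihood; the source does not state a noise magnitude, and 0.3 (≈ ±35%
per observation) is a typical inter-animal spread for organ-level
biodistribution measurements. Blood punctures are generated with the same
four replicates per time point since the identity of punctured animals is
not described. What the generator deliberately does *not* emulate: inter-
animal kinetic variability (a single θ generates all animals),
limit-of-quantification censoring, assay-specific error (e.g., fluorescence
calibration for IR780), and any free-released-drug kinetics. Passing
recovery tests therefore demonstrate the estimation machinery is correct
and calibrated under its own assumptions; they say nothing about structural
adequacy for real biodistribution data.

## Problem sizes used in the shipped experiments

The recovery experiment in the test suite fits the PACA low-dose design
(184 records) with a 20 000-iteration chain (50% burn-in); the sampler
calibration check uses 1e5 iterations on a 2-D Gaussian; conservation is
checked for 100 random parameter vectors across both bounds families; the
noise-free identifiability check uses a 3 000-iteration chain plus MAP
polish. These sizes give stable statistics at interactive runtimes.

## Known limitations

- **Tempered likelihood flattens recovery.** Because of the 1/N, adding data
  does not sharpen the posterior. In the shipped recovery experiment the
  medians of the well-identified parameters (χ_rich, k_kidneyEl, k_de) land
  within a factor ~1.5 of their generating values, but parameters whose
  generating value sits far from the geometric center of a wide prior box
  (P, generating value 3.9 against a box centered at 1.0; the correlated
  uptake pair k_ab0/k_sab0) are pulled toward the box center and can miss a
  factor-2 target. The MAP estimate does not suffer from this pull and
  recovers noise-free data exactly; the discrepancy is a property of the
  tempered posterior, not of the sampler (see the analysis accompanying the
  recovery test).
- The exchange scheme assumes a well-mixed quasi-steady capillary; organs
  with partial, heterogeneous perfusion are outside its accuracy.
- Fixed kinetic rates are placeholders of realistic magnitude, not measured
  values; conclusions about the fixed routes (feces, bile, lymph) should
  not be drawn from the defaults.
- No free-drug submodel: the loaded substance is assumed to track its
  carrier throughout.
- Human extrapolation, inhalation/oral dosing and tumor compartments are out
  of scope.
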