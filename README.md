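# nanopbpk

Whole-body PBPK modeling and Bayesian parameter estimation for
intravenously administered nanobiomaterials in rat.

Nanoparticle drug carriers (polymeric particles, lipid carriers) redistribute
a loaded substance over organs in ways governed by a handful of kinetic
properties: vascular permeability, tissue partitioning, renal clearance, and
uptake/release by organ-resident macrophages. `nanopbpk` provides, as a
tested library plus a thin command line:

- a **physiologically based pharmacokinetic (PBPK) model** of the rat with 14
  main compartments (arterial/venous blood, upper airways, tracheobronchial
  and pulmonary regions, liver, spleen, kidney, heart, brain, GI tract, rest,
  lymph nodes, GI lumen), 8 phagocytizing-cell sub-compartments and 4
  clearance routes (urine, feces, hepatic metabolism, lymphatics), driven by
  an IV bolus into arterial blood;
- **Bayesian estimation** of its six free parameters
  θ = (χ_rich, P, k_kidneyEl, k_ab0, k_sab0, k_de) with a robust adaptive
  Metropolis (RAM) sampler in log-parameter space, under the squared-log-ratio
  likelihood

      ln P(D|θ) = −(1/N) Σᵢ [ln(predictedᵢ / observedᵢ)]²

  and a bounded Jeffreys (1/θ) prior;
- **model evaluation** via the average absolute fold error,
  AAFE = 10^[(1/N) Σ |log₁₀(pred/obs)|], overall and per organ;
- **local sensitivity analysis** of blood exposure as elasticities
  S = (ΔAUC/AUC)/(Δp/p) with 10% one-at-a-time perturbations;
- a **synthetic biodistribution generator** reproducing the five published
  dose-group designs (PACA-Cbz at 0.5 and 3.5 µg/g bw; LipImage™ 815 at
  0.046, 0.15, 0.46 µg/g bw; sacrifice at 1 h–14 d, four animals per time
  point, serial blood punctures) with multiplicative log-normal noise — the
  in vivo datasets themselves are unpublished.

See `docs/methods.md` for the model equations, assumptions, defaults and
known limitations.

## Worked example

Generate a synthetic low-dose PACA-Cbz dataset, score the generating
parameters against it, and rank parameter influence on blood exposure:

```bash
$ nanopbpk synth --design paca_low --seed 1 --out paca_low.csv
wrote 184 records to paca_low.csv

$ nanopbpk evaluate --dataset paca_low.csv --out aafe.json
overall AAFE 1.2328 over 184 records

$ nanopbpk sensitivity --design paca_low --out sens.csv
wrote 6 elasticities to sens.csv
```

The 184 records are 7 organs × 5 sacrifice times × 4 animals plus 11 blood
punctures × 4 animals. The AAFE of 1.23 says model and data differ by 23% on
(geometric) average — pure measurement noise here, since the data were
generated at the evaluated parameters with noise σ = 0.3 (the theoretical
large-N AAFE for that noise level is exp(0.3·√(2/π)) ≈ 1.27). Per-organ
values in `aafe.json` range from 1.20 (heart) to 1.31 (spleen). The
elasticity table,

```
parameter,elasticity,auc_base,auc_perturbed,perturbation_fraction
chi_rich,-0.3048,6.5156,6.3171,0.1
P,-0.1908,6.5156,6.3913,0.1
k_kidneyEl,-0.1879,6.5156,6.3932,0.1
k_de,0.0017,6.5156,6.5167,0.1
k_ab0,-0.0007,6.5156,6.5152,0.1
k_sab0,-0.0000,6.5156,6.5156,0.1
```

ranks vascular permeability as the strongest lever on blood AUC (a 10%
increase in χ_rich lowers blood exposure by ≈3%), with partitioning and renal
clearance close behind and the macrophage parameters nearly inert for this
output — they move organ retention, not blood levels.

Fitting the posterior to a dataset (writes draws, a summary JSON of medians
with 90% credible intervals per parameter, and a run manifest):

```bash
nanopbpk fit --dataset paca_low.csv --seed 11 --iterations 20000 --out fit/
```

The same operations are available as library calls
(`nanopbpk.generate_synthetic`, `nanopbpk.run_fit`, `nanopbpk.summarize`,
`nanopbpk.evaluate_fit`, `nanopbpk.oat_scan`).

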