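# sorensen

A whole-body glucose–insulin–glucagon simulator (22 nonlinear compartmental
mass balances: brain, heart/lungs, gut, liver, kidney, periphery, plus
pancreatic insulin secretion and normalized glucagon), extended with a
four-compartment gastrointestinal transit chain (stomach → jejunum →
delay → ileum) whose absorption flux `r_oga` feeds the gut glucose balance.
Only the corrected forms of the classic rate laws are implemented (renal
excretion slope 0.011, renal insulin clearance driven by the heart/lungs
concentration, stabilizing labile-pool sign, peripheral-uptake basal
gradient); the historically circulated erroneous variants exist solely as
regression fixtures.

On top of the simulator:

- **Protocols** — IVGTT glucose boluses, insulin boluses, continuous insulin
  infusions and oral glucose loads, integrated from an exact basal
  equilibrium, with venous observation conversions (0.84 blood / 0.925
  plasma on peripheral vascular glucose).
- **Estimation** — weighted least squares with inverse-squared-expectation
  weights, the four-step multistart identification pipeline (gut chain →
  secretion submodel → joint → perturbed restarts), finite-difference
  asymptotic covariance `σ²[JᵀF⁻¹J]⁻¹` with percent CVs.
- **Bayes** — Metropolis-within-Gibbs posterior sampling of
  `(log θ, σ²)` with an inverse-gamma σ² full conditional, nine chains
  started on a 3×3 lattice of the uniform prior box, and empirical 95%
  credibility regions from 20×20 bivariate histograms.
- **Fixtures** — declared synthetic stand-ins for the historical digitized
  absorption (27 points) and secretion (25 points) curves, with
  mean-proportional noise, labelled STANDIN and byte-reproducible per seed.

## Parameter presets

- `appendix_a1` — the corrected literature parameterization (pancreas
  glucose sensing in mg/dl).
- `table3_after` — the OGTT-recalibrated secretion parameters (mM sensing;
  pool/provision converted at 7000 pmol/U).
- Gut chain: `simo_after` (default), `simo_prior`, `simo_table3_after`.

## CLI

```sh
sorensen check                                  # analytic desk checks
sorensen simulate --protocol ivgtt.yaml --out series.csv
sorensen make-fixtures --kind roga --out roga.csv
sorensen fit --step 1 --obs roga.csv --out fit.json
sorensen mcmc --obs obs.csv --params beta,M2 --theta-opt 15.6,0.25 --out chains.csv
```

A protocol YAML looks like:

```yaml
protocol:
  route: iv_glucose_bolus    # iv_insulin_bolus | iv_insulin_infusion | oral_glucose | none
  dose: 0.5                  # g/kg here; U/kg, mU/kg/min or g per route
  duration: 180.0
params: appendix_a1
```

Every command writes a JSON run manifest (presets, seeds, tolerances,
config hash) next to its output. Exit codes: 0 success, 2 configuration
error, 3 numerical failure.

## Notes

- `basal_initialization` defaults to an exact-equilibrium mode: the printed
  initial-condition cascade fixes all normalization anchors, then the state
  is Newton-refined so every derivative is below 1e-6 per minute.  A
  `paper` mode (CLI `--paper-ic`) reproduces the printed initial conditions
  verbatim.
- Glucagon is simulated in normalized units (basal = 1); absolute glucagon
  concentrations are not reported.
- The gut transit chain is exactly non-identifiable under a
  `k_js ↔ (k_gj + k_rj)` swap with rescaled jejunum outflows; recovery
  tests are therefore self-consistency checks started near the generating
  values, and noisy refits of all five rates carry large (~90% CV)
  uncertainty on `k_js`/`k_gj` by design of the 0–300 min sampling window.
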