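# ptrkit

A method-development toolkit for **proton transfer reaction time-of-flight
mass spectrometry (PTR-ToF-MS)** quantitation of volatile organic compounds
(VOCs), aimed at analysts setting up targeted methods — choosing a reagent
ion and reduced-field operating point, correcting raw peak tables, and
validating quantitation against gravimetric standards.

## What it does

PTR-ToF-MS ionizes trace VOCs in a drift tube with a chosen reagent ion
(H₃O⁺, NO⁺, or O₂⁺) and counts the product ions. Converting count rates to
mixing ratios rests on pseudo-first-order reaction kinetics:

    n_A = Σ I_products / ( t · Σ_r k_r I_r )

where *t* is the ion residence time in the drift tube, *I_r* the reagent-ion
count rates, and *k_r* the ion–molecule capture rate constants. `ptrkit`
implements every step of that chain:

- **Drift-tube physics** — number density, reduced electric field
  E/N = (U/d)/N in Townsend, drift velocity v_d = μ₀N₀(E/N), reaction time
  t = d/v_d, and the Wannier effective collision temperature for non-thermal
  drift conditions.
- **Capture-rate kinetics** — the Langevin rate k_L = 2πq√(α/μ) and its
  parametrized-trajectory extension for polar molecules,
  k = K(x)·k_L with x = μ_D/√(2αk_BT_eff), so rate constants reflect the
  actual collision energy at each E/N.
- **Peak-table handling** — a plain-text time × m/z dialect, and the
  detector *transmission curve* (natural cubic spline through reference-mix
  knots) that corrects mass-dependent detection efficiency.
- **Ion corrections** — saturated reagent-beam channels recovered from
  minor isotopologue monitors (m/z 21.02, 39.03, 30.99, 33.99 Th), the
  hydronium–water-cluster population that must join the quantitation
  denominator at low E/N, ¹³C/protonated-ion deconvolution of M+1 peaks,
  and the daily QC rules (impurity fractions, fragment-ratio stability).
- **Fragmentation analysis** — segmentation of stepped voltage ramps,
  attribution of product channels to a spiked parent compound by their time
  evolution, branching-ratio tables vs E/N, and humid-vs-dry comparisons.
- **Quantitation & optimization** — mixing ratios with cluster chemistry,
  sensitivity (cps/ppbV) profiles vs E/N, and recommended operating points
  balancing sensitivity against spectral purity.
- **Gravimetric validation** — diffusion-tube release rates from weight
  loss vs rates implied by the measured mixing ratio and oven flow, with
  accuracy (error %) and repeatability (CV %) statistics.
- **Forward simulation** — every input above can be generated with known
  ground truth (spike kinetics, saturated beams with isotopologues,
  programmed branching and transmission, Poisson counting noise), so the
  whole pipeline is testable without an instrument.

## Worked example

Simulate a decanal/NO⁺ headspace spike measured across a stepped voltage
ramp (600 → 200 V, i.e. 144 → 48 Td), then attribute the product ions and
tabulate branching ratios:

```python
from ptrkit.synthetic import (RampConfig, simulate_ramp_run,
                              default_transmission_curve)
from ptrkit.workflow import analyze_ramp_run

cfg = RampConfig(seed=42)                      # decanal with NO+, Poisson noise
table = simulate_ramp_run(cfg)
analysis = analyze_ramp_run(table, cfg.schedule,
                            default_transmission_curve(),
                            compound="decanal")
print(analysis.products)
print(analysis.branching.rounded())
```

```
[39.02, 41.03, 43.04, 57.07, 67.05, 81.08, 95.09, 137.13, 155.14]
            144   132   120   108   96    84    72    48
product_mz
39.02         9  <NA>  <NA>  <NA>  <NA>  <NA>  <NA>  <NA>
41.03        19    10  <NA>  <NA>  <NA>  <NA>  <NA>  <NA>
43.04         9    11     9  <NA>  <NA>  <NA>  <NA>  <NA>
57.07         8     9     8  <NA>  <NA>  <NA>  <NA>  <NA>
67.05         5  <NA>  <NA>  <NA>  <NA>  <NA>  <NA>  <NA>
81.08        13     8     6  <NA>  <NA>  <NA>  <NA>  <NA>
95.09        15    10     7  <NA>  <NA>  <NA>  <NA>  <NA>
137.13        8     8    10     9     6     5     6     6
155.14       13    43    60    91    94    95    94    94
```

Each column is one ramp plateau (integer Td); entries are percent of the
attributed product-ion signal. The picture is the one that drives method
choice for aldehydes with NO⁺: at the energetic 144 Td end the spectrum is
dominated by alkyl fragments, while at 96–108 Td the hydride-abstraction
quasi-molecular ion [M−H]⁺ at m/z 155.14 carries ≳90% of the signal —
maximal specificity. The confounder channel programmed into the simulation
(m/z 83.09, drifting independently of the spike) is correctly rejected by
the attribution rule, and the two low-E/N water-adduct channels, which only
switch on in the last plateaus, are a documented blind spot of noisy
attribution (see `docs/methods.md`).

The sensitivity profile from the same run shows why low E/N pays off —
count rate per ppbV at the reference peak rises from 1.1 (144 Td) to
28.0 cps/ppbV (48 Td):

```python
from ptrkit.workflow import sensitivity_profile
from ptrkit.library import load_compound_library

lib = load_compound_library()
profile = sensitivity_profile(table, cfg.schedule,
                              default_transmission_curve(),
                              lib["decanal"].params,
                              analysis.products, reference_mz=155.14)
print(profile.points.round(1))
# 144: 1.1   132: 4.0   120: 6.1   108: 10.5
#  96: 12.5   84: 14.8   72: 17.4   48: 28.0  (cps/ppbV)
```

The same stages are available from the shell:

```sh
ptrkit simulate --kind ramp --seed 42 --out ramp.tsv
ptrkit fragment --input ramp.tsv --compound decanal --out branching.tsv
ptrkit simulate --kind diffusion --seed 1 --out diffusion.tsv
ptrkit quantify --input diffusion.tsv --compound decanal --out rates.tsv
ptrkit calibrate --rates-csv src/ptrkit/data/reference_diffusion_rates.csv \
    --out accuracy.tsv
```

## Layout

- `src/ptrkit/kinetics.py` — drift-tube physics, capture rates
- `src/ptrkit/peaktable.py` — peak-table I/O, transmission curves
- `src/ptrkit/ion_corrections.py` — isotopologue extrapolation, ¹³C, QC
- `src/ptrkit/fragmentation.py` — ramp segmentation, attribution, branching
- `src/ptrkit/quantify.py` — concentrations, sensitivity, optimal E/N
- `src/ptrkit/gravimetric.py` — diffusion-tube statistics
- `src/ptrkit/synthetic.py` — forward simulators with ground truth
- `src/ptrkit/workflow.py`, `src/ptrkit/cli.py` — pipeline wiring and CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
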