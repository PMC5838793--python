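# Methods

This note documents the models implemented in `ptrkit`, the defaults they
ship with, what the forward simulator does and does not emulate, and the
design choices made where the problem was genuinely open.

## Drift-tube model

The drift tube is described by voltage *U*, pressure *p*, temperature *T*,
length *d*, and the reduced mobility μ₀ of the reagent ion in the buffer
gas. From these:

- number density N = p/(k_B·T);
- reduced field E/N = (U/d)/N, quoted in Townsend (1 Td = 10⁻¹⁷ V·cm²).
  Integer-rounded Td values are used as labels (matching how operating
  points are conventionally quoted); unrounded values are carried
  internally;
- drift velocity v_d = μ₀·N₀·(E/N), with N₀ the Loschmidt number density;
- reaction time t = d/v_d.

**Drift length.** Commercial instruments do not always publish *d*. The
default, d = 9.6 cm, is calibrated so that the canonical operating point —
600 V at 2.30 mbar and 110 °C — sits at 144 Td; the same length then
reproduces the whole eight-step voltage ladder (144, 132, 120, 108, 96, 84,
72, 48 Td for 600…200 V) after integer rounding. It is exposed on
`DriftConditions` for instruments with a known geometry.

**Mobilities.** μ₀ defaults to 2.76 cm²V⁻¹s⁻¹ for H₃O⁺ in air and
2.8 cm²V⁻¹s⁻¹ for NO⁺ and O₂⁺ — typical literature-scale values, both
overridable. Reaction times within a run use the bare reagent ion's
mobility for all species.

**Buffer gas.** Treated as air with mean molar mass 28.8 Da; the effect of
humidity on the buffer mass is neglected.

## Effective temperature and capture rates

Drift fields make ion–neutral collisions superthermal. The mean ion kinetic
energy follows the Wannier form

    KE_ion = (3/2)k_B T + (1/2)(m_ion + m_buffer) v_d²,

and the center-of-mass collision energy with a neutral of mass M replaces
the superthermal part by its reduced-frame share M/(m_ion + M). The
effective temperature T_eff is the temperature with that mean energy; at
zero field it equals the gas temperature exactly.

Capture rate constants use the parametrized-trajectory treatment evaluated
in Gaussian units: the Langevin rate k_L = 2πq√(α/μ) is scaled by

    K(x) = (x + 0.5090)²/10.526 + 0.9754   (x < 2)
    K(x) = 0.4767·x + 0.6200               (x ≥ 2)

with x = μ_D/√(2αk_B·T_eff). K is continuous at the branch point (1.5734
from both sides), equals 1 at x = 0 to within 3·10⁻⁵ (the Langevin limit),
and is non-decreasing. The same parametrization is applied to all three
reagent ions, including O₂⁺ charge transfer, for want of a better model of
the latter's kinetics; measured rate constants can be supplied as
per-compound, per-reagent overrides and take precedence everywhere.

Polarizabilities and dipole moments in the bundled compound library are
representative values for the study compounds; users with better data
should override them — rate constants enter linearly, so a 10% error in k
maps to a 10% error in concentration.

## Peak tables and the transmission curve

Peak tables are pre-integrated, centroided channel intensities (cps) on a
uniform time grid with per-bin voltage and a humidity flag; mass-axis
calibration and centroiding are upstream of this package. The text dialect
is documented in `peaktable.py`.

The detector's mass-dependent transmission is fitted from a certified
aromatic mix measured at a known mixing ratio (100 ppbV per component):
each reference channel's measured/expected ratio becomes a knot, the knots
are normalized to a maximum of 1 (the absolute scale is unobservable — see
below), and a natural cubic spline interpolates between them. Outside the
knot range the curve is clamped to the end-knot values; splines extrapolate
wildly and no information exists out there. Correction divides every
channel by the curve and is guarded against double application.

Because the expected rates are computed from the *uncorrected* primary-ion
monitor, the fitted knots carry an unknown common factor (the transmission
at the monitor channel). This cancels exactly in quantitation as long as
the same curve corrects both product and primary channels, which is how the
pipeline applies it; max-normalization is therefore purely cosmetic.

## Primary-ion handling

Main reagent-beam channels saturate the detector, so beam currents are
recovered from minor-isotopologue monitors scaled by natural abundance:

| beam | monitor (Th) | factor |
|---|---|---|
| H₃O⁺ (19.02) | 21.02 (¹⁸O) | 497.6 |
| (H₂O)H₃O⁺ (37.03) | 39.03 (¹⁸O, 2 O atoms) | 248.8 |
| NO⁺ (30.00) | 30.99 (¹⁵N) | 273.7 |
| O₂⁺ (31.99) | 33.99 (¹⁶O¹⁸O, 2 O atoms) | 248.8 |

The factors derive from ¹⁸O/¹⁶O = 0.2005/99.757 and ¹⁵N/¹⁴N = 0.364/99.636
and are configurable; ¹³C/¹²C defaults to 0.0108.

At low E/N the hydronium water cluster is a second reactive reagent
population: its share of the reagent current exceeds 10% below ~90 Td, and
it enters the quantitation denominator additively, Σ_r k_r·I_r over the
bare ion and the cluster. The cluster's capture rate defaults to the same
parametrization evaluated with the cluster mass (37 Da) and the analyte's
α/μ_D, overridable per compound. The NO⁺ water cluster stays below the
reactivity threshold and is excluded from the denominator by design,
though its fraction is still reported.

M+1 peaks above a molecular ion can mix the ¹³C isotopologue with a genuine
protonated product (ligand switching from water clusters followed by
dissociative collision). The deconvolution subtracts the expected ¹³C
share, M+1_corr = M+1_meas − M·n_C·r₁₃, clamps negative residuals to zero
with a warning, and flags channels whose M+1 exceeds the pure-isotopologue
expectation.

**QC rules.** Impurity fractions are checked per mode — O₂⁺ < 2% in
hydronium mode, NO₂⁺ < 3% in nitrosonium mode, NO⁺+NO₂⁺ < 5% in dioxygenyl
mode (the published thresholds are ambiguous about which mode the 3% NO₂⁺
check belongs to; it only makes sense for NO⁺ operation and is implemented
there). Fragment-ratio stability passes when every measurement lies within
±2% of the series mean.

## Fragmentation workflow

A run spikes one compound into a humid headspace and steps the voltage down
in one-minute plateaus. Defaults and choices:

- **Settling windows.** The first 10 s of each plateau are discarded
  (voltage settling), and bins before spike_time + 15 s in the plateau
  containing the spike (pre-addition baseline and headspace equilibration).
  Both configurable.
- **Attribution.** A channel is attributed to the parent when its
  post-spike rise exceeds 5 baseline Poisson standard deviations *and* its
  trace tracks the total-product trace with Pearson r ≥ 0.95. The
  correlation is evaluated in the spike window (spike to the end of its
  plateau), where drift conditions are constant and every product is
  exactly proportional to the headspace concentration. Channels that only
  switch on at later plateaus (low-E/N adducts) are admitted by a
  within-plateau proportionality test against the already-attributed
  products. The published workflow attributes "by eye"; these thresholds
  are this package's operationalization.
- **Known limitation.** The within-plateau test is exact for noiseless data
  but noise-limited: when the within-plateau signal variation is small
  compared with counting noise, late-onset channels are not confirmed and
  the low-E/N columns renormalize over the remaining products. Supplying
  the candidate set from the compound library sidesteps this for targeted
  work.
- **Branching ratios.** Per plateau, mean transmission-corrected cps per
  product, normalized to percent of the product sum (so columns sum to 100
  by construction), rounded to integers for reporting. Products below 2% in
  every plateau are dropped; declared isotopologue partners can be merged
  into their parent channel before normalization. Because shares are
  ratios, they are invariant to the absolute signal level and to the
  spike's time profile within a plateau.

## Quantitation, sensitivity, optimal conditions

Mixing ratio = n_A/N·10⁹ ppbV with n_A from the pseudo-first-order
relation. Sensitivity is quoted the way practitioners use it: raw
(uncorrected) cps at a chosen reference peak divided by the concentration
computed from *all* product ions. The recommended operating point is the
most sensitive plateau among those where the diagnostic ion carries at
least a purity floor (default 75%) of the product signal, ties broken
toward lower Td (gentler conditions); if no plateau qualifies, the best
available is returned with a warning.

## Gravimetric validation

Diffusion-tube release rate from weight loss: rate = Δm/Δt (ng/min).
Spectrometric rate from the measured mixing ratio: rate = x·Φ/V_m·M, with
Φ the oven flow in sccm and V_m = 22414 cm³/mol — the molar volume at
273.15 K and 1013.25 mbar, adopted as the sccm reference state
(configurable; flow controllers differ). Error is 100·(grav − spec)/grav,
reported to one decimal; this convention is fixed because the published
validation table is not internally sign-consistent (its butanoic-acid row
is flipped relative to the others, and two further rows differ by one
rounding unit from their printed means — the bundled reference CSV
reproduces the five self-consistent rows exactly). Replicates aggregate as
mean ± sample SD (n−1); repeatability is the CV in percent.

## Forward simulator

The generators produce every input the pipeline consumes, with ground
truth:

- **Spike kinetics**: c(t) = c_max(1−e^{−Δt/τ_r})e^{−Δt/τ_d} with
  τ_r = 5 s, τ_d = 2000 s — a fast equilibration and slow headspace
  depletion standing in for the qualitative rise-then-decay of a syringe
  addition. The default spike concentration is 1000 ppbV, the ppm-scale
  headspace of a percent-level aqueous standard, which puts the product-ion
  sum at the 10⁴ cps scale.
- **Count scales**: reagent beams at 10⁶ cps source-level with main
  channels clipped at 10⁵ cps (forcing the isotopologue path), products
  10³–10⁵ cps, Poisson noise applied per time bin (1 s default).
- **Branching vs E/N**: piecewise-linear in Td through per-compound anchor
  tables (normalized to 100 per column), patterned on the measured
  fragmentation of the study compounds — decanal/NO⁺, hexanoic
  acid/H₃O⁺, ethyl-phenol/O₂⁺, and a short-chain aldehyde whose programmed
  pattern yields a ≥4-fold sensitivity gain at 72 vs 144 Td.
- **Cluster chemistry**: hydronium cluster fraction 0.30 − 0.002·Td
  (clipped to [0.01, 0.5]): ~1% at 144 Td, ~13% at 84 Td, ~20% at 48 Td.
- **Transmission**: a smooth log-normal-shaped curve peaked near 120 Th.
- **Confounder**: one channel ramping linearly from run start,
  independent of the spike, to exercise the attribution correlation rule.
- **Diffusion runs**: constant mixing ratio derived from the programmed
  release rate, flow, and V_m; reagent ions cycling in fixed blocks
  (5 min each on the bench; tests and the acceptance script use 1-min
  blocks, a problem-size choice that leaves every count rate unchanged);
  the paired gravimetric record carries the exactly consistent weight
  loss.

What the simulator does **not** emulate: headspace partitioning physics
(concentrations are programmed, not derived from Henry's law), detector
dead-time beyond hard clipping, mass-axis drift, peak-shape and centroiding
artifacts, chemical noise/background ions, and humidity-dependent
sensitivity beyond a programmed branching shift. Passing round-trip tests
therefore demonstrates the correctness and noise behavior of the *analysis
chain*, not the fidelity of any instrument model: recovering the programmed
truth shows the pipeline inverts the forward model it claims to invert,
with Poisson-limited precision.

## Numerical choices

- Gaussian-units constants (q = 4.8032·10⁻¹⁰ esu, k_B = 1.3807·10⁻¹⁶
  erg/K) and isotope abundances are centralized in `constants.py`.
- Channel lookup matches m/z within ±0.005 Th (two-decimal channel labels).
- Degenerate correlation inputs: two numerically constant traces count as
  perfectly correlated, one constant against one varying as uncorrelated.
- Negative corrected counts (¹³C subtraction) clamp to zero with a warning.
- Transmission evaluation floors at 10⁻⁶ to guard against spline overshoot
  between sparse knots.
- Branching percentages are stored unrounded; integer rounding happens only
  in the reporting view.
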