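# Methods

`revpot` implements the reversal-potential route to the coupling
stoichiometry of electrogenic secondary active transporters, end to end:
equilibrium thermodynamics, experiment design, a synthetic proteoliposome
flux-assay generator, and the inference stage that turns replicate tracer
time courses into a stoichiometry assignment.

## The equilibrium model

A transport cycle is a fixed-stoichiometry reaction over species terms
(νᵢ, zᵢ): signed copies moved inward per cycle and integer valence.
Counter-transported species carry negative ν.  At a clamped membrane
potential ΔΨ = Ψ_in − Ψ_out (outside grounded), the free energy of one
inward cycle, in mV-equivalents, is

    G = s · Σᵢ νᵢ log₁₀(c_in,i / c_out,i) + Q · ΔΨ,     Q = Σᵢ νᵢ zᵢ

with the Nernst slope fixed at **s = 60 mV/decade**.  Temperature is not a
parameter: the 60 mV convention (rather than 59.2 mV at 25 °C) is what
reproduces the integer voltages this kind of experiment is designed and
reported in.  Solutions are treated as ideal (activities = concentrations);
no activity-coefficient correction is applied.

G < 0 drives influx, G > 0 efflux, and the root in ΔΨ is the reversal
potential

    E_rev = −(s/Q) · Σᵢ νᵢ log₁₀ rᵢ,    rᵢ = c_in,i / c_out,i.

For the canonical n Na⁺ : m S²⁻ symporter this reduces to
E_rev = −60/(n/m − 2) · ((n/m) log₁₀ r_Na + log₁₀ r_S); for a neutral
substrate (a sugar) to E_rev = −60 · ((m/n) log₁₀ r_G + log₁₀ r_Na).
Electroneutral cycles (Q = 0, e.g. n/m = 2 with a divalent anion) have no
reversal potential and every routine raises rather than returning a number.
Because each candidate n:m maps to a distinct E_rev under known gradients,
one no-flux voltage bracketed by influx below and efflux above pins the
stoichiometry without any kinetic model.

Directional vocabulary follows the liposome convention: an "inwardly
directed" gradient means a higher concentration outside (r < 1).  The two
benchmark systems are VcINDY (3 Na⁺ : 1 succinate²⁻; under a 1:4 inward Na⁺
gradient and 10:1 outward succinate gradient E_rev = +48.4 mV) and vSGLT
(1 Na⁺ : 1 galactose).

### A note on the static-head relation

`static_head_ion_gradient` implements the power-law rule conventionally
quoted for static-head experiments, r_ion = (1/r_S)^(n/m) — e.g. a 10:1
substrate gradient ↦ a 1:1000 ion gradient for n/m = 3.  The exact
zero-voltage equilibrium condition Σνᵢ log rᵢ = 0, however, solves to the
inverse exponent r_ion = (1/r_S)^(m/n): a 10-fold substrate accumulation is
balanced by a 10^(1/3) ≈ 2.2-fold inward Na⁺ gradient, while a 1:1000 ion
gradient would hold a 10⁹-fold accumulation.  Both are exposed: the
conventional rule as the named helper, the exact balance through
`equilibrium_substrate_ratio`, whose correctness is enforced by the
free-energy-root property test.

## Experiment design

- `predict_candidate_potentials` evaluates every candidate n:m under a
  gradient set; electroneutral candidates are flagged, not dropped.
- `solve_gradients_for_targets` inverts the design: two candidate/target
  pairs give a 2×2 linear system in (log₁₀ r_Na, log₁₀ r_S).
- `check_separability` fails a design whose closest electrogenic pair is
  under 15 mV apart — the resolution credited to a K⁺/valinomycin
  ("chemical patch clamp") voltage clamp, whose compositions come from
  `potassium_for_voltage` (k_out = k_in · 10^(V/60)).
- `balance_osmolarity` pads buffers with choline chloride under ideal
  van 't Hoff counting (2 particles per monovalent salt, configurable per
  salt; no osmotic coefficients) over a fixed 20 mM Tris/HEPES background.

## Synthetic flux assays

The generator emulates the data shape of a proteoliposome radiotracer
assay: triplicate internalized-CPM time courses at several clamped
voltages, sampled at (0, 5, 15, 30, 60, 120) s, with a t = 0 baseline
drawn once per batch and shared across voltages.

The population-mean internal substrate concentration follows

    ds/dt = −k · s_out · sat · (1 − e^(−G/s₆₀)) − λ(t) · s

integrated by fixed-step RK4 (dt = 0.25 s).  G is re-evaluated at the
instantaneous internal concentration, so E_rev is an exact fixed point and
the simulated flux sign always agrees with the thermodynamic direction; the
exponential form is one admissible choice among laws that vanish at G = 0
with the right sign — the data constrain only that point and the signs.
Defaults, chosen once as the study conditions:

- `rate_scale` k = 0.05 s⁻¹ with s_out the external substrate: produces
  unmistakable influx/efflux within 30–60 s at |ΔΨ − E_rev| ≈ 36 mV and a
  sub-noise residual drift at 0.4 mV off equilibrium, the regime of the
  benchmark time courses.  An optional Michaelis factor sat = s_out/(s_out+K_m)
  is off by default.
- Vesicles: 400 nm spheres (the extrusion pore size; true internal
  diameter is not knowable from filtration data) and 10¹⁰ vesicles per
  sample.  At 1 µM internal substrate this is ≈ 20 molecules per vesicle;
  per-vesicle occupancy is Poisson (`draw_vesicle_occupancy`).
- Counts: CPM = moles × specific activity (60 Ci/mmol, tritiated
  substrate) × 2.22·10¹² dpm/Ci × counting efficiency (0.3 for ³H, ~0.9
  for ¹⁴C), ≈ 1.3·10⁴ CPM at baseline.  Replicates are Poisson draws
  around the mean trajectory.
- Baseline scatter: the t = 0 value is multiplied by unit-mean lognormal
  jitter, CV 0.05 by default (sugar-transporter scenarios with strong
  batch scatter are emulated with CV ≈ 0.2 plus 5-s normalization).
- Leak: first-order loss of internal substrate switching on at 30 s,
  off by default, flagged protein-mediated (rate_scale = 0 silences it),
  mirroring the observed late-onset loss at negative potentials without
  claiming a mechanism.

What the generator does **not** emulate: filter-binding artifacts,
vesicle-size heterogeneity, clamp drift or rundown of the K⁺ gradient,
per-vesicle stochastic trajectories, and saturation kinetics beyond the
optional Michaelis factor.  Passing recovery tests therefore show the
inference logic is sound under the stated noise model, not that every real
assay will be as clean.

## Inference

1. **Flux calls** — pooled OLS of CPM on time per voltage; two-sided
   t-test on the slope at α = 0.05.  Positive significant slope = influx,
   negative = efflux, otherwise "none"; the slope CI contains zero exactly
   when the call is "none".  The default fit window starts at the first
   post-dilution timepoint (t > 0): the t = 0 sample is a separately
   collected batch baseline whose loading scatter would otherwise inflate
   the regression variance.  With `leak_expected` the window is capped at
   30 s, before the leak contributes; with `normalize_t` (division by the
   replicate-mean CPM at 5 s, the remedy for strong baseline scatter) the
   window starts at the normalization anchor.
2. **Reversal-potential estimate** — a "none" call bracketed by influx
   below and efflux above is the point estimate, with the flanking flux
   voltages as the bracket.  Absent such a call, the zero crossing is
   interpolated linearly between adjacent voltages.  The model interpolates
   the fitted *slopes* rather than the ΔCPM values: a shared scattered
   baseline offsets every ΔCPM by the same random amount (skewing the root
   by tens of mV) while leaving slopes untouched.  ΔCPM
   (initial − later counts, positive = efflux) is still computed and
   reported as the voltage–ΔCPM table, the flux analog of an I–V curve.
   Calls all in one direction raise an indeterminate-equilibrium error.
3. **Assignment** — a candidate is *excluded* when significant flux was
   called within 10 mV of its predicted E_rev **and** the direction is
   inconsistent with it: influx at V places the true E_rev above V, so it
   refutes candidates predicting E_rev ≤ V (efflux the mirror image).  The
   direction condition matters near equilibrium: a clamp at +48 mV against
   a true E_rev of +48.4 mV leaves a genuine sub-noise influx that an
   α = 0.05 test occasionally detects, and a direction-blind rule would
   then refute the *true* candidate.  Among survivors, the candidate
   nearest the estimate is assigned if within 10 mV (and inside the
   bracket); "unassigned" is a valid outcome.  The 10 mV tolerance sits
   between clamp rounding (~1 mV) and the 15 mV design separability floor.

Under the default study conditions (triplicates at +12/+48/+84 mV, true
cycle 3 Na⁺ : 1 succinate²⁻), the acceptance suite verifies that the
pipeline assigns 3:1 in at least 95 of 100 seeded runs and never assigns
1:1.

## Numerical and degenerate-input choices

- Equilibrium tolerance for `flux_direction`: |G| < 10⁻⁶ mV-equivalents.
- The flux law's exponent is clamped to ±50 to avoid overflow at extreme
  gradients; internal concentration is floored at zero (a warning is
  logged if the floor is hit).
- Electroneutral inputs raise `ElectroneutralCycleError` everywhere;
  missing species raise `MissingSpeciesError` naming the species.
- All randomness flows from one `numpy` Generator per experiment; fixed
  seeds give bit-identical tables, and every CLI manifest records the seed
  and a config hash.
- Rational stoichiometries are accepted by the thermodynamic core;
  candidate enumeration uses small integers.

## Known limitations

- The kinetic law is phenomenological; rates, K_m and binding order are
  out of scope, as is Hill analysis.
- Voltage clamping is assumed ideal and constant; uncoupled conductances
  (e.g. Cl⁻) and K⁺-coupled transporters are outside the model.
- The sugar-transporter (vSGLT-style) scenario is covered at the level of
  the neutral-substrate equation and the normalization machinery; its
  original buffer compositions are not public, so no numeric reconstruction
  of that dataset is attempted.
- pH-gradient/CCCP clamping is not modelled.
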