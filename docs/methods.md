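# Methods

## Model structure and assumptions

The model reduces organismal nitrogen disposal to a single well-mixed blood
compartment exchanging with an implicit liver. Everything outside the blood —
hepatocyte interiors, muscle, gut — is assumed to equilibrate freely (no
transporter kinetics, free diffusion across membranes), so the only volume
that affects concentrations is the blood volume. Total ammonia is one pool:
no NH₃/NH₄⁺ speciation anywhere in the kinetics.

The urea cycle is represented by its first committed step (CPS1) alone. To
preserve the cycle's 2-nitrogens-per-urea stoichiometry, a duplicate of the
CPS1 flux ("urea for balance") consumes a second ammonia and discards its
product: urea gains `V_CPS1` while ammonia loses `2·V_CPS1`. This makes the
nitrogen bookkeeping exact — `V·d(nh3 + gln + 2·urea)/dt` equals absorption
minus the two excretions at every instant, an identity the test suite checks
both analytically on flux vectors and numerically along trajectories.

Spatial zonation of the acinus is translated into temporal switching: blood
traverses the sinusoid in 4.3 s, spending 2/3 of it (2.87 s) exposed to the
zone 1–2 enzymes (CPS1, glutaminase) and 1/3 (1.43 s) to the zone 3 enzyme
(glutamine synthetase). Absorption and excretion run unconditionally. The
resulting sawtooth in the ammonia trace is an artifact of this
representation, which is why the steady state is defined on the peak
envelope. Glutaminase activity is taken equal in zones 1 and 2, without
cooperativity (Hill coefficient 1); glutaminase cooperativity and reduced
zone-2 activity are deliberately excluded, as is arterial/venous
heterogeneity and any meal structure (nutrition is a continuous supply).

## Parameters

| parameter | value | unit | origin |
|---|---|---|---|
| blood volume | 6.59 | L | linear in body mass, 5.2 L at 70 kg, for 88.7 kg |
| liver mass | 1561 | g | average male liver |
| sinusoid transit | 4.3 | s | phase split 2.87 + 1.43 |
| GLS Vmax / Km | 28.54 / 4.0 | mmol/min, mM | 91.4 nmol/min/mg × 20% protein × 1561 g |
| CPS1 Vmax | 8.05 / 8.47 / 8.78 | mmol/min | NAG-adjusted per diet (71/100/122 g/day) |
| CPS1 Km | 0.35 | mM | |
| GLUL Vmax / Km / Ki | 12.3 / 0.15 / 0.6 | mmol/min, mM, mM | 0.47 μmol/15 min/mg × 25% × 1561 g |
| NH₃ absorption | 0.492 / 0.693 / 0.845 | mmol/min | protein × 16% N × (1 − 12.7% fecal loss) / 14 / 1440 |
| NH₃ / urea excretion | (0.004, 0.244) / (0.008, 0.343) / (0.012, 0.417) | mmol/min | reference-range daily amounts, constant over 24 h |
| initial state | (0, 5.5, 0) | mM | ammonia, urea, glutamine |

Dietary intakes between the three anchors are piecewise-linearly interpolated
on the printed anchor values (for CPS1 Vmax and both excretion rates);
extrapolation outside 71–122 g/day is refused rather than guessed. The
maximally NAG-activated CPS1 capacity (45 nmol/min/mg → 17.56 mmol/min) is
retained as a documented constant but never used directly: the diet-adjusted
values are stored as printed because the underlying NAG dose–response data
are not part of this package. Cirrhosis multiplies CPS1 Vmax by 0.70 and GLUL
Vmax by 0.20; the CPS1 heterozygote multiplies the *diet-adjusted* CPS1 Vmax
by 0.50 (the plausible alternative — halving the maximal capacity before NAG
adjustment — was rejected because disease simulations are defined as
departures from the normal baseline).

All rates are stored in mmol/min and concentrations in mM; the single
conversion to per-second dynamics happens inside the integrator.

## Numerics

The switching schedule is fixed and periodic, so the ODE is integrated
piecewise with solver restarts at precomputed phase boundaries — no event
detection, no discontinuity-induced step rejection. Within each phase the
smooth system is solved with LSODA at rtol 1e−8 / atol 1e−10 mM (the Km
scale of 0.15–4 mM against μM ammonia is only mildly stiff; LSODA switches
as needed), with 24 interior output points per phase so per-cycle extrema
are resolved. Halving the tolerances and doubling the output density moves
the detected steady state by far less than 0.1% (tested).

Two guards keep the state physical: substrate concentrations are clamped at
zero inside the rate laws (solver overshoot cannot generate negative
fluxes), and the zero-order effluxes are multiplied by a C¹ smoothstep that
vanishes below 1e−6 mM — constant-rate excretion is otherwise undefined at
zero stock. The floor sits three orders of magnitude below every
concentration of interest and is absent from the SBML export, which carries
the ideal rate laws.

Steady-state detection extracts the per-cycle maximum of ammonia and the
relative rate between consecutive peaks, `(p_k − p_{k−1})/(p_{k−1}·Δt)·100`
in %/s. Convergence requires |rate| < 0.002%/s over the final **three**
consecutive cycles — one compliant pair would be vulnerable to an
accidentally flat pair early in a transient. Ammonia is reported from the
final peak; urea and glutamine from the final state, since their intra-cycle
oscillation is negligible in relative terms. An unmet criterion at the
horizon yields `converged=False`, never an exception.

Two readouts deserve flags. First, the CPS1-heterozygote scenarios do not
meet the 0.002%/s criterion at the default 774 s horizon (their final peak
rates are ≈0.006–0.008%/s); the reported 774 s peak values are within ~1.5%
of the fully converged levels reached by ~1550 s, and it is the 774 s values
that correspond to the conventionally quoted numbers for these scenarios.
The grid honestly reports `converged=False` for those rows. Second, the
early-kinetics summary (`initial_average_rate`) is expressed in μmol/s *per
litre of blood* (μM/s). An amount-based reading of the conventional
"μmol/s" figure would be inconsistent with the model's own nitrogen influx
(0.492 mmol/min ≈ 8.2 μmol/s total), whereas the per-litre reading is
consistent with both the quoted rates and the steady state; the unit is
stated explicitly rather than silently reinterpreted.

## Design choices

- **Brain partition default.** The blood→brain conversion offers the pure pH
  ratio `10^(pH_blood − pH_brain)` = 2.512 (default) and the exact
  Henderson–Hasselbalch ratio `(1 + 10^(pKa−7.0))/(1 + 10^(pKa−7.4))` =
  2.491 at pKa 9.25. The simple ratio is the default because the
  conventionally quoted brain levels (44 μM from 17.5 μM; 101 from 40.3) are
  reproduced by 2.512, the pKa→∞ limit of the exact form; both modes are
  exposed.
- **Two percent-change baselines.** The grid reports disease effects against
  the same-diet normal row (isolates the condition) and against the
  recommended-diet normal cell (total departure from the healthy reference);
  the cirrhosis effect averages ≈41% on the first convention and spans
  ≈39–128% on the second.
- **Sweep grids.** Default activity fractions are 0.1–1.5 for CPS1 and 0–1.5
  for GLUL in steps of 0.1. CPS1 at exactly zero is allowed but reported as
  non-converged: with a constant nitrogen influx and no urea production the
  blood pool cannot settle.
- **SBML export without a dedicated SBML library.** The export is generated
  directly as SBML L3V2 XML (lxml), with the zonation encoded as two events
  toggling 0/1 gate parameters via the phase clock
  `t − cycle·floor(t/cycle)`. Round-tripping is verified by re-parsing.

## What the simulations do and do not show

All inputs are published constants; there is no synthetic data generator and
no randomness anywhere — identical configurations produce byte-identical
outputs. The acceptance script and test suite therefore exercise the exact
study conditions (three diets, three conditions, 774 s horizon), and an
independent algebraic oracle — the duty-cycle-averaged CPS1 balance
`(2/3)·2·Vmax·x/(Km+x) = absorption − excretion`, solved by bisection —
brackets every simulated steady state within 10%.

Limitations carried over from the model structure: GLUL deficiency shows
almost no steady-state effect here, whereas strongly elevated ammonia is
observed in GLUL-deficient patients — the CPS1:GLUL exposure ratio implied
by the zonation scheme likely overweights CPS1, so disease effect sizes may
be conservative. Blood is homogeneous (no arterial/venous gradient), intake
is continuous (no postprandial peaks), urea excretion does not adapt to urea
levels (urea is marginally stable and drifts slightly off 5.5 mM rather
than being regulated), and no transporters, cofactor pools, or muscle
ammonia buffering are represented.
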