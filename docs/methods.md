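# Methods

## Scope and assumptions

stenoflow evaluates 0D (algebraic) pressure–flow relations across a single
arterial stenosis.  The lesion is a rigid, circular, area-varying tube:
unobstructed diameter D₀, throat diameter Dₛ, length Lₛ.  Blood is Newtonian
and incompressible (defaults ρ = 1060 kg/m³, μ = 3.5 mPa·s, overridable
everywhere).  The flow enters as a prescribed periodic mean-velocity signal
u(t); outlet impedance, wall elasticity, network effects and 3D flow
features are outside the models by construction.  Eccentric lesions keep a
circular lumen of the same throat area, offset from the axis: the models
are area-based, so eccentricity is carried as metadata only.

Rigid-wall and Newtonian assumptions are standard for peri-stenotic
pressure estimation: atherosclerotic segments are stiff, and the vessel
calibres covered (4 mm–5 cm) put shear rates in the Newtonian plateau.

## Model terms and coefficients

All three models share the structure viscous + turbulence + inertial
(+ a constant "continuous" component in the Itu model).  Coefficients that
matter, with defaults:

| symbol | meaning | default | notes |
|---|---|---|---|
| Kt | empirical turbulence coefficient (Q\|Q\| closures) | 1.52 | overridable; 1.0 in the oldest formulation |
| Ku | empirical inertial coefficient | 1.2 | |
| Kc | continuous-term coefficient | 0.0018·α² | α from cyclic f (Hz) |
| Cm | dimensional constant in Cε | 1 kg²·s/m⁴ | |
| L  | inertial length | Lₐ | `inertial_length="stenosis"` selects Lₛ |
| t_ref | unit-cycle time factor of the cubic closure | 1 s | see below |
| p̄ₒ | reference proximal pressure for FFR | 13332.2 Pa (100 mmHg) | explicit in every output |

The Womersley number is computed with the cyclic frequency f = 1/T in Hz,
α = R₀·√(ρf/μ); with the default blood this gives
α ≈ 14 at aortic calibre and α ≈ 1.1 at coronary calibre, the intended
regimes of the Itu corrections.  Using angular frequency instead would
inflate α by √(2π) and is deliberately not done.

### The cubic turbulence term

The dissipation closure starts from ε = Cε·u³/ℓ, integrates it over the
lesion volume (approximated as Q̄·t over one cycle) and divides by the mean
flow, giving a pressure contribution Cε·t_ref·u³/ℓ with ℓ = Lₐ and an
implicit time factor equal to the 1 s cycle.  In flow-rate form the term is

    Δp_turb = Cε · t_ref · Q³ / (Lₐ · A₀³),   Cε = 2·Cm·ν·(1/Aₛ − 1/A₀)²·S_D/ρ.

Two readings of the Cε severity factor are defensible from the closure's
typography; the package makes the choice explicit and selectable:

* `severity-scaled` (default): multiply by S_D, divide by ρ.  Cε then has
  density units (the only dimensionally coherent option for the cubic
  pressure term), grows superlinearly with severity — consistent with the
  turbulence term overtaking the viscous term in severe lesions — and
  reproduces the expected magnitude of the term (≈ 1·u³ for the
  aortic-calibre lesion at S_D = 0.7).
* `severity-divided` / `severity-multiplied`: divide or multiply by the
  full ρ·S_D product.  Provided for sensitivity analysis; both make the
  viscous/turbulence balance essentially severity-independent
  (`severity-divided`) or turbulence-saturated (`severity-multiplied`).

Every evaluation logs the form used and stores Cε in the output
coefficients.  The closure is calibrated for T = 1 s cycles; other periods
evaluate with t_ref unchanged and emit a warning.

### Integral coefficients and the lumen profile

Rvc and Lu require a radius profile R(x), which a 0D description does not
fix.  The default is a cosine bump, R(x) = R₀ − (R₀−Rₛ)(1 − cos 2πx/Lₛ)/2,
symmetric about the throat; a conical taper and CSV-sampled profiles
(monotone-cubic interpolated) are provided.  The profile shape changes Rvc
by tens of percent (cosine vs conical ≈ 1.3× at 60 % severity), so the
shape tag is recorded in every output.  Quadrature is composite Simpson
starting at 1001 nodes with step-halving until the result changes by less
than 1e-8 relative; agreement with a ×100-resolution trapezoid reference is
tested to 1e-6.

### Upstream segment

Each geometry carries an upstream entrance length (default 4·D₀).  Its
fully developed Poiseuille drop can be folded into the viscous term with
`include_upstream=True`; the default is off, since the models describe the
lesion itself and the upstream drop is below ~3 % of the lesion drop in all
benchmark cases.

## Inlet waveforms

* **BC1** — u(t) = u₀ + A·sin(2πft), analytic derivative.  Study values:
  u₀ = 0.02, A = 0.01 m/s at aortic scale; u₀ = 0.2, A = 0.1 m/s at
  coronary/carotid scale (amplitude = half the mean in both).
* **BC2** — synthetic physiological pulse: diastolic pedestal a plus a Hann
  (cos²) systolic wave of width 0.35·T centred at 0.2·T, normalised to an
  exact requested mean; period 1 s.  The peak/mean ratio defaults to 1.6 so
  that, with means matched to BC1, the peak inlet Reynolds number stays in
  the same ≤ 500 band at both vessel scales (aortic: Re ≈ 492; coronary:
  Re ≈ 388).  The shape is C¹ with an analytic derivative and is fully
  determined by its logged parameters — no randomness.

What BC2 does *not* emulate: measured waveform microstructure (dicrotic
notch, reverse-flow phase, beat-to-beat variability) and scale-specific
waveform shapes (coronary flow is diastolic-dominant; the same generic
pulse is used at both scales).  Quantities that depend only on low-order
moments of u(t) — cycle means, E[u³], term shares — are robust to this;
claims tied to the fine temporal shape of a measured pulse are not, and
results under BC2 should be read as "for a generic physiological pulse of
this peakedness".  E[u³]/ū³ is 1.375 for BC1 and 1.18 for the default BC2.

Sampled waveforms (CSV, one period, uniform grid) are evaluated by
trigonometric interpolation, giving spectral derivatives; generated
waveforms use their analytic derivatives.

## Cycle averaging and reported statistics

All cycle statistics use composite Simpson on 1000 intervals (1001 nodes)
over exactly one period; the models are memoryless, so one cycle suffices.
Reported per model and case:

* Δp̄ — signed cycle average of the total drop;
* per-term cycle averages of |term|, and two contribution metrics:
  `mean-abs` (default; average |term| over the sum of average |terms|) and
  `at-mean-flow` (terms evaluated at Q = Q̄, dQ/dt = 0, the bar-chart
  convention at the average velocity — inertial share zero by definition);
* FFR = 1 − Δp̄/p̄ₒ with class positive (≤ 0.75) / negative (≥ 0.80) /
  intermediate (open interval between); both boundaries closed.  Values
  outside [0, 1] (severe lesions can predict Δp̄ > p̄ₒ) are reported as
  computed and flagged, never clamped.

The steady two-coefficient form Δp = A·Q + B·Q³ (A = μKv/2πR₀³,
B = Cε·t_ref/LₐA₀³) reproduces the dynamic cycle average up to the cubic
Jensen gap B·(E[Q³] − Q̄³); for the study inlets this is at most
0.375 × (turbulence share) relative, under 20 % on all benchmark cases, and
the inertial term averages to zero over any full cycle.

## Numerical choices

* Simpson everywhere (cycle averages and profile integrals); tolerances as
  above.  Doubling the sampling changes Q̄ by < 1e-9 relative.
* Degenerate inputs: Ds = 0 is rejected at construction (singular areas);
  S_D = 0 gives Cε = 0 exactly and a pure Poiseuille + inertia model;
  flow reversal in BC1 (A ≥ u₀) warns but evaluates (the comparators use
  Q|Q| precisely to keep sign fidelity; the cubic term is odd in Q).
* Determinism: identical manifests produce byte-identical result CSVs; all
  generators are parameter-driven with no random state.

## Benchmark grid

`run_sweep(default_manifest())` evaluates the four lesion families
(G1 aortic short, G2 carotid short, G3 aortic long, G4 coronary eccentric)
at S_D ∈ {0.5, …, 0.9} under BC1 and BC2 (G3 under BC1 only), for all three
models — 105 rows, each carrying the complete coefficient set (Kv, Kt, Ku,
Kc, Cε, L, Rvc, Lu, α) for audit.  These problem sizes run in seconds and
are the ones used by the test suite and the acceptance script.

## Known limitations

* Absolute FFR values depend on the assumed 100 mmHg reference pressure;
  only classification logic and relative behaviour are meaningful without a
  measured p̄ₒ.
* The printed severity-dependence of the viscous/turbulence balance for the
  eccentric lesion in the source study (ratios spanning ~18× between 50 %
  and 90 % severity) is steeper than any reading of the Cε closure can
  produce: both the viscous coefficient and Cε scale as (A₀/Aₛ)², leaving
  only Lₐ², S_D and O(1) factors of severity dependence.  The package
  reports the ratios its equations imply (≈ 2.5, 1.0, 0.55 cycle-averaged;
  ≈ 3.5, 1.4, 0.76 at the mean-flow point).
* Very severe lesions (S_D ≥ 0.8 at coronary scale) predict drops beyond
  the physiological pressure head; these are extrapolations of the
  closures, flagged via `ffr_in_range`, and should not be read
  quantitatively.
* 3D reference solutions (RANS/laminar CFD) are out of scope; agreement
  statements against CFD require externally supplied reference data via the
  `compare` interfaces.
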