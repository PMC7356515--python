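# Methods

## Model structure and assumptions

The simulator couples a two-compartment tumor balance to three therapy
channels.  Proliferating volume x₁ grows exponentially at the net rate
a − n (growth minus natural necrosis) and is killed at rate E, the
combined therapy effect; every unit of killed or necrosed volume is moved
into the necrotic compartment x₂ and never washes out.  Total volume
x₁ + x₂ therefore obeys d(x₁+x₂)/dt = a·x₁ exactly and is nondecreasing:
therapy in this model *retards* growth by removing proliferating tissue,
it does not shrink the total mass.  This is a deliberate minimalism — the
model resolves macroscale dose–effect structure, not tissue clearance.

Each drug channel is a linear one-compartment PK pair: a serum level with
first-order clearance driven by the dose-rate input, and an effect-site
level driven by the current tumor–drug effect times the serum level.  The
effect-site coupling makes the PD feed back into the PK of the effect
site; this is a plain nonlinear coupling evaluated from the instantaneous
state.  Slow peripheral distribution compartments (fat, muscle) are
intentionally absent.

Radiotherapy is driven in physical units: the daily scheduled dose (Gy)
enters as a constant rate over the dosing day, decays with clearance c_r,
and is normalized by C50_r (Gy/day) inside the response surfaces.  Because
only the normalized ratio ever enters an equation, the model is invariant
to the unknown Gy → concentration conversion constant, and no explicit
constant is introduced.

## Interaction surfaces

Agent levels are normalized to potency: serum-independent effect-site
levels over their half-effect concentrations, and the tumor over C50_t
expressed as percent of the initial volume (so x₁ = V₀ normalizes to
100/50 = 2).  Each ordered pair is collapsed through
I = Un_A + Un_B + σ·Un_A·Un_B and Effect = Emax·Iᵞ/(1+Iᵞ).  Choices made
where the formulation was genuinely open:

* **Emax of drug–drug terms** — the arithmetic mean of the two drugs'
  Emax values: symmetric, bounded, and reduces to the single-drug Emax
  when they agree.
* **One σ and one γ** are shared by all six surfaces (the parameter set
  defines one of each); per-surface overrides can be added via config.
* **Drug-presence gating** — the tumor's normalized level is positive even
  without treatment, so an ungated tumor–drug surface would report a kill
  at zero dose and the untreated run would not reduce to its exponential
  closed form.  Each tumor–drug term is therefore exactly the Hill
  surface while its channel holds any drug (serum, effect site, or a
  running infusion) and exactly zero otherwise.  Gating on the running
  infusion as well as the state matters twice over: it keeps the
  right-hand side smooth from the first instant of a treated run, and a
  gate on the effect-site level alone would deadlock the bootstrap
  ẋe = −c·xe + Et·x (the effect site could never leave zero).  Drug–drug
  terms need no gate; their index vanishes with the levels.

## Parameters

Defaults are the published mouse-study values; all are overridable via
config file, `--param`, or `CombinedParameters.replace`.

| symbol | meaning | default | unit |
|---|---|---|---|
| a | tumor growth rate | 0.25 | 1/day |
| n | necrosis rate | 0.10 | 1/day |
| c_a | AG clearance | 0.1825 | 1/day |
| c_i | IM clearance | 11.6/24 ≈ 0.4833 | 1/day |
| c_r | RT drive clearance | 3/24 = 0.125 | 1/day |
| C50_a | AG half-effect | 0.44 | mg/mL |
| C50_i | IM half-effect | 32·10⁻⁶ | mg/mL |
| C50_r | RT half-effect | 20 | Gy/day |
| C50_t | tumor half-effect | 50 | % of V₀ |
| Emax_a/i/r | max efficacies | 0.70 / 0.43 / 0.50 | fraction |
| γ | response exponent | 2.5 | – |
| σ | synergy coefficient | 4 | – |
| V₀ | initial tumor volume | 1000 | mm³ |
| unit_rate | effect → kill-rate conversion | 1.0 | 1/day |

Notes on unit conventions.  The IM clearance is a literature value of
11.6 mL/h re-expressed per day and interpreted as a rate under a unit
(1 mL) distribution volume, keeping the printed numeral intact.  The RT
clearance 3/24 treats "3 hours in a day" as a daily rate as printed.
Maximum efficacies are stored as fractions of their percent forms.  The
Hill surfaces are dimensionless, so the combined effect E is multiplied
by `unit_rate` (default 1/day) to become the kill rate; this keeps the
effect aggregation and the tumor balance dimensionally explicit.

The LQ radiobiology module ships α/β = 10 Gy with α = 0.3 Gy⁻¹ and a
repair half-time T½ = 1 h — α is not pinned by the source tables, and
0.3/Gy with a ~1 h sublethal-damage repair half-time are conventional
magnitudes for lung tumor tissue; both are configurable.  Exposure
durations are converted to hours before forming μt (μ = ln 2/T½).  The
LQ module does not drive the default pipeline: protocols are given in
Gy per day and the physical dose drives x₅ directly.  An optional
BED-style re-weighting of daily fractions by the incomplete-repair
effect (`incomplete_repair_weighted_schedule`) is provided but off by
default.

## Dosing protocols

Days are 1-based; day k spans continuous time [k−1, k).  Administration is
a constant infusion over the dosing day (an instantaneous bolus mode is
available per schedule).  Weekly dosing lands on days 1, 8, 15, 22, 29.
The three radiotherapy protocols over the 30-day horizon:

1. 5 Gy once weekly (25 Gy total);
2. 5 Gy on days 1–3, 2 Gy on days 15–17 (21 Gy total) — "after two weeks"
   is mapped to day 15, two full weeks after day 1;
3. 5 Gy day 1 plus 0.075 Gy microfractions on days 2–3, then 2 Gy day 15
   plus 0.075 Gy on days 16–17 (7.3 Gy total).  The microfraction timing
   is not pinned by the protocol statement; they are placed on the two
   following days to mirror Protocol 2's 3-day span (a same-day delivery
   variant is available).

Drug dosing is assumed to start on day 1 simultaneously with
radiotherapy.

## Numerics

* Fixed-step classical RK4, default step 0.01 day, steps aligned to the
  day boundaries where the piecewise-constant inputs jump.  Fixed
  stepping makes every run bit-for-bit reproducible; there is no
  randomness anywhere in the package.
* With γ = 2.5 the surfaces scale as I^2.5 near zero level, so the
  right-hand side is only twice continuously differentiable at therapy
  onset; step halving 0.01 → 0.005 moves the day-30 proliferating volume
  of a protocol run by ≈ 2·10⁻⁶ relative (the smooth untreated run
  converges below 10⁻⁹).  The default step is well inside the asymptotic
  regime for every reported quantity.
* The sigmoid is evaluated as Iᵞ/(1+Iᵞ) for I ≤ 1 and 1/(1+I⁻ᵞ) above,
  which saturates without overflow at the very large normalized levels
  the IM channel reaches.
* The incomplete-repair g-factor switches to its Taylor series
  1 − x/3 + x²/12 − x³/60 below μt = 10⁻⁶ to avoid cancellation.
* Negative state components (possible at a discontinuity undershoot, and
  systematically in the legacy model where the inhibitor balance carries
  a near-zeroth-order drain) are clipped to zero at stage entry and after
  each step, with one logged warning per run.
* Trajectory CSVs print 10 significant digits for diff-stable output.

## Experiment runners

`run_control`, `run_protocol`, `synergy_sweep` (σ varied, all else
fixed) and `resistance_sweep` (γ varied at σ = 4) summarize day-30
volumes; contrasts are percent relative differences of total volume, and
the synergy contrast is the fold-reduction between the extreme σ values.
All headline quantities in the README are produced by these runners; the
acceptance script reruns them from scratch.

## Known limitations

* Under the default coefficients the immunotherapy effect-site level
  normalized by C50_i = 32·10⁻⁶ mg/mL is of order 10³ within hours of the
  first weekly 0.2 mg/mL dose, so every surface containing that channel
  saturates to its Emax almost immediately.  The averaged combined effect
  then carries a large protocol-independent component (≈ 0.4/day against
  a net growth of 0.15/day), and protocol, synergy and response contrasts
  computed on the day-30 totals are correspondingly modest: ≈ 4.6%
  between Protocols 2 and 1, ≈ 5.1% between Protocols 3 and 2, a
  1.16-fold σ = 1 → 8 reduction, and a γ = 8 vs γ = 1 change of ≈ −8.6%.
  Reports for this class of model cite substantially larger contrasts
  (tens of percent, several-fold); reaching them would require operating
  the surfaces in their sensitive region (normalized levels of order
  one), which the printed C50 values and doses do not produce.  In
  particular, with interaction indices above 1 a larger γ *steepens* the
  surfaces toward full effect, so increased γ behaves as increased
  sensitivity, not resistance, on these trajectories.
* No washout of necrotic tissue: total volume cannot decrease, so the
  model cannot represent regression of total mass.
* The LQ module's α and T½ defaults are conventional, not fitted; the
  fractionated-input polynomial is an evaluator for user-supplied
  coefficients only.
* Mouse-scale parameterization throughout; no human scaling, toxicity,
  or normal-tissue complication modelling.
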