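# minpkpd

A minimal pharmacokinetic–pharmacodynamic (PKPD) simulator for tumor growth
under combined therapy in non-small-cell lung cancer (NSCLC) models:
antiangiogenic drug (Bevacizumab-type), immune checkpoint inhibitor
(Nivolumab-type) and radiotherapy, with explicit drug-synergy and
patient-response dials.  It is aimed at modellers and treatment-planning
researchers who want to compare dosing protocols *in silico* on a compact,
fully deterministic mechanistic model parameterized from mouse studies.

## The model

Eight coupled nonlinear ODEs track the proliferating tumor volume x₁ (mm³),
the necrotic volume x₂, and serum/effect-site levels for each therapy
channel (x₃/xe₃ antiangiogenic, x₄/xe₄ immunotherapy, x₅/xe₅ radiotherapy
drive):

    ẋ1  = (a − n)·x1 − E·x1        ẋ2  = n·x1 + E·x1
    ẋ3  = −c_a·x3 + u_a(t)         ẋe3 = −c_a·xe3 + Et_a·x3
    ẋ4  = −c_i·x4 + u_i(t)         ẋe4 = −c_i·xe4 + Et_i·x4
    ẋ5  = −c_r·x5 + u_r(t)         ẋe5 = −c_r·xe5 + Et_r·x5

Therapy effects come from Hill response surfaces over potency-normalized
levels Unᵢ = Uᵢ/C50ᵢ.  Each pair of agents (tumor–drug and drug–drug) is
collapsed into an interaction index

    I = Un_A + Un_B + σ·Un_A·Un_B,      Effect = Emax · Iᵞ / (1 + Iᵞ),

where σ sets the degree of synergy (isoboles bow inward for σ > 0) and γ
the sigmoidicity, used here as a patient responsiveness/resistance dial.
The combined kill rate averages the three tumor–drug and three drug–drug
terms:

    Et_all = (Et_a + Et_i + Et_r)/3,  Ed_all = (E_ai + E_ar + E_ir)/3,
    E = (Et_all + Ed_all)/2.

A linear-quadratic (LQ) radiobiology module provides −ln S = αD + βD² cell
survival, the incomplete-repair g-factor for protracted exposure, and the
fractionated input form; radiotherapy protocols are specified directly in
Gy per day.  See `docs/methods.md` for assumptions, units and numerical
choices.

## Worked example

Compare the untreated control with radiotherapy Protocol 1 (5 Gy once
weekly) and Protocol 2 (5 Gy × 3 days, then 2 Gy × 3 days after two weeks),
both on top of weekly 0.171 mg/mL antiangiogenic and 0.2 mg/mL
immunotherapy dosing, from an initial tumor of 1000 mm³ over 30 days:

```sh
$ minpkpd control --out-dir out
control: end total 149361.9 mm3 (active 90017.1, necrotic 59344.8)
$ minpkpd protocol --id 1 --out-dir out
protocol1: end total 1931.4 mm3 (active 4.9, necrotic 1926.5)
$ minpkpd protocol --id 2 --out-dir out
protocol2: end total 1842.1 mm3 (active 1.7, necrotic 1840.4)
```

Untreated, the proliferating volume grows exponentially at a − n = 0.15/day
to 90,017 mm³ (the model's closed form V₀·e^{(a−n)·30}).  Under either
combination protocol the kill term drives the proliferating volume to a few
mm³ within the month; the end totals are dominated by necrotic volume
accumulated in the first days.  Protocol 2's front-loaded fractions kill
slightly faster early, ending ≈ 4.6% below Protocol 1.

The same comparisons are available from Python:

```python
import minpkpd as mp

params = mp.default_combined_parameters()
p1 = mp.run_protocol(1, params)
p2 = mp.run_protocol(2, params)
print(mp.relative_difference(p2, p1))   # -4.62 (% of Protocol 1 volume)

sweep = mp.synergy_sweep(params, sigma_values=[1, 8])
print(sweep.contrast)                   # 1.163-fold reduction from sigma=1 to 8
```

A sweep over the synergy coefficient (Protocol 3 background):

```sh
$ minpkpd sweep --sweep-param sigma --values 1,8 --out-dir out
 sigma              label  end_total_mm3  end_active_mm3  end_necrotic_mm3
   1.0 protocol-3 sigma=1    2138.272055       12.836078       2125.435977
   8.0 protocol-3 sigma=8    1838.475863        2.476594       1835.999269
fold_reduction_end_total: 1.1631
```

Every run writes a trajectory CSV (daily states, total volume and effect
terms) and a JSON summary carrying a full provenance block (all effective
parameters plus a schedule digest) from which the run can be reproduced
bit-for-bit.

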