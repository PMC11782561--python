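# tcesim

Mechanistic PKPD simulation of cytokine release after CD3 T-cell-engager
(TCE) dosing.

TCE bispecific antibodies redirect T-cells against tumor cells. Their main
clinical liability is cytokine release syndrome (CRS), which is strongest at
the first dose: a second dose given shortly after the first releases far
less IL6, even though tumor killing is preserved. `tcesim` implements a
mechanistic explanation of that behavior — a finite pool of naive T-cells
that is consumed by activation and takes weeks to replenish — as a
reusable ODE simulator with a dosing-regimen engine, a two-dose scenario
battery, a ±20% one-at-a-time parameter sensitivity analysis, and a simpler
depletable-pool comparator model. It is aimed at pharmacometricians
exploring dosing intervals and step-up dosing strategies for CD3 TCEs.

## The model

A one-compartment PK model drives a 13-state PD system (all cell pools in
cells/µL, IL6 in pg/mL, time in hours):

- **PK** — dC_pla/dt = −(CL/V)·C_pla; IV bolus dosing adds
  dose·BW/V to C_pla.
- **T-cell activation** — naive T-cells (baseline k_in,naive/k_apop =
  1600 cells/µL) are activated at the Hill rate
  fK_act = E_max,act·C_pla^h / (C_pla^h + EC50_act^h) and traverse five
  transit compartments (rate k_delay) before becoming *desensitized*:
  still cytotoxic, but silent in cytokine release.
- **Cytokine release** — dCyt/dt = k_in,cyt·(1 + fK_cyt) − k_deg,cyt·Cyt,
  with fK_cyt = E_max,cyt·Hill(C_pla)·(Tact₅)^α: only the *fifth* activated
  compartment releases IL6, producing the few-hour lag between dosing and
  the cytokine peak.
- **Tumor killing** — all activated plus desensitized cells kill
  (fK_kill = E_max,kill·C_pla/(C_pla+EC50_kill)·T_kill); dying cells pass
  through three transit compartments. An empirical IL2 autocrine term
  proliferates T-cells and is inhibited at high effector:target (E:T)
  ratios.

Because cytokine release needs naive-derived cells in the fifth transit
compartment while killing also works through desensitized cells, the model
*uncouples* CRS risk from efficacy: a second dose at day 7 kills tumor
cells nearly as well as the first but releases <1% of the cytokine
increment.

## Worked example

```python
import tcesim as ts
from tcesim.dosing import DoseRegimen, il6_peak_per_dose, recovery_time, simulate_regimen

params = ts.ParameterSet()                      # published mouse defaults
regimen = DoseRegimen(dose_per_bw=0.5, body_weight=0.02, dose_times=(0.0,))
result = simulate_regimen(params, regimen, t_end=45 * 24.0)
print(il6_peak_per_dose(result))
print(recovery_time(params, regimen))
```

Running `python examples/01_single_dose.py` prints:

```
initial plasma TCE:        4.3478 ug/mL
IL6 peak:                  97.5 pg/mL at 3.3 h (baseline 10)
IL6 at 2 h post dose:      49.2 pg/mL
naive T-cell nadir:        11.3 cells/uL (baseline 1600)
95% pool recovery after:   28.2 days
```

A single 0.5 mg/kg dose (4.35 µg/mL initial plasma concentration in a 20 g
mouse) drives IL6 from its 10 pg/mL baseline to a ~97 pg/mL peak within
hours, while the naive T-cell pool collapses from 1600 to ~11 cells/µL and
needs about four weeks to refill — which is why cytokine release only fully
returns for a second dose given 28 days later.
`python examples/02_interval_battery.py` quantifies that: the second/first
IL6 peak ratio is 0.105 at a 1-day interval, 0.166 at 14 days, 0.613 at 21
days and 0.910 at 28 days.

The other examples cover the sensitivity tornado (`03`), the pool-model
comparison (`04`) and synthetic observation tables (`05`). A thin CLI wraps
the same functions: `tcesim simulate`, `tcesim battery`,
`tcesim sensitivity`, `tcesim compare-pool`,
`tcesim synthetic-observations`.

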