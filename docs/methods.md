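# Methods

## Model structure and assumptions

`tcesim` simulates systemic IL6 release in a tumor-bearing mouse given
repeated IV bolus doses of a CD3 T-cell engager. The central hypothesis is
that the blunted cytokine release at a second, closely spaced dose is a
*T-cell state shift*, not tumor-cell depletion: activation consumes the
finite naive T-cell pool, the activated cells desensitize within hours
(retaining cytotoxicity but not cytokine release), and the naive pool
refills only on the slow homeostatic timescale 1/k_apop.

The 13 ODE states are the plasma TCE concentration, naive T-cells, five
activated transit compartments, desensitized T-cells, IL6, live tumor
cells and three dying-tumor transit compartments. Key structural
assumptions:

- PK is linear one-compartment (CL, V); no target-mediated disposition or
  FcRn recycling. PD does not feed back on PK, so plasma concentration
  superposes linearly across doses.
- Activation is a Hill function of plasma concentration alone
  (E_max,act = 1.5/h, h = 2, EC50 = 1 µg/mL). At the studied dose
  (0.5 mg/kg → 4.35 µg/mL) activation is effectively complete: the naive
  pool empties within hours and stays empty while C_pla remains above
  ~0.1 µg/mL.
- Only the fifth activated transit compartment drives IL6 release
  (fK_cyt = E_max,cyt·Hill_2.5(C_pla)·Tact₅^α with α = 2); the transit
  chain (k_delay = 2.5/h, mean delay 5/k_delay = 2 h) reproduces the
  few-hour lag between dosing and the cytokine peak. fK_cyt is used as a
  dimensionless multiplier of the cytokine synthesis rate, taking the
  tabulated E_max,cyt value at face value with the state in cells/µL; the
  published units for this constant are not self-consistent with that
  role, and this package resolves the ambiguity by reproducing the
  calibrated numerical behavior.
- All T-cell states die at the common rate k_apop = 0.01/h; activated and
  desensitized (not naive) cells proliferate at the IL2-driven rate, which
  is inhibited above an effector:target ratio of ~7. The E:T ratio counts
  *all* T-cells over *all* tumor cells, including the dying-transit
  compartments — a literal reading of the accounting; the dying pools are
  transient and small, so the choice is not load-bearing.
- Tumor cells were not measured in the underlying study; their absolute
  scale matters only through the E:T ratio and the initial condition
  Tumor(0) = 0.1·Tnaive(0) (initial E:T = 10).

Transit compartments 2–4 are not written out in the source description;
they follow the same pattern as the printed first and fifth compartments
(first-order transit, apoptosis, IL2 proliferation), the standard
transit-chain structure consistent with both printed endpoints.

## Parameters

Defaults (bundled in `tcesim/data/defaults.yaml`) are the published
calibrated mouse values; see `ParameterSet` for the full list with units.
Two derived quantities are locked by definition rather than stored:
k_in,cyt = 10 pg/mL · k_deg,cyt (so the drug-free IL6 baseline is exactly
10 pg/mL) and Tnaive(0) = k_in,naive/k_apop = 1600 cells/µL. The dosing
conversion assumes an IV bolus into the central compartment with a default
body weight of 0.020 kg; the source study states neither route nor body
weight, and both are exposed as regimen fields.

## Numerics

Integration uses LSODA with rtol 1e-8 / atol 1e-10 and piecewise
integration between bolus events; the sample at a dose time reports the
post-dose state. Signal functions clamp sub-zero state excursions to zero
inside the integrator rather than raising, and a post-hoc check rejects
any trajectory dipping below −1e-9 before clipping the stored output at
zero. The output grid defaults to 0.1 h; halving it changes reported IL6
peaks by far less than 0.1%. When the tumor denominator of the E:T ratio
falls below 1e-12 cells/µL the ratio is capped at 1e12, which drives the
IL2 inhibition to its saturated limit instead of dividing by zero.

## Derived metrics

- **Per-dose IL6 peak** — the window maximum of IL6 from each dose time to
  the next (or to the simulation end). The 2 h post-dose sample is
  computed separately as the analogue of the single in-vivo draw, which
  was taken as reflective of the maximum.
- **Cmax ratio** — second-window peak divided by first-window peak for two
  equal 0.5 mg/kg doses. The ratio is *second/first* (the inverse
  orientation also appears in the source material; this package documents
  and uses second/first throughout).
- **Recovery time** — first time after the post-dose nadir at which Tnaive
  regains 95% of baseline. "Fully replenished" is quantified as 95% — a
  conventional but arbitrary cut, exposed as `threshold_frac`. With
  default parameters this is 28.2 days.
- **OAT sensitivity** — each non-tumor parameter scaled by (1 ± 0.2), all
  others at default, ranked by the larger absolute deviation of the
  perturbed Cmax ratio from baseline (span). The four tumor-kinetics and
  killing constants are excluded by construction. I_max sits at its bound
  of 1 and is perturbed downward only; k_in,cyt moves with k_deg,cyt. The
  initial state is recomputed self-consistently under every perturbation,
  so k_in,naive and k_apop shift the baseline pool as well as its
  kinetics.

Two empirical notes on these metrics under default parameters, both
established with an independent R/deSolve re-implementation of the same
equations. First, the interval–ratio curve is not strictly monotone: it is
flat near 0.105 for intervals up to ~5 days with a dip of ~1e-4 (residual
drug from the first dose adds to the second bolus and slightly potentiates
the cytokine Hill term while the transit-chain throughput is pinned at
k_in,naive), before rising steeply through 14, 21 and 28 days. The
package's tests therefore assert the robust form of the trend (ratio ≪ 1
at 1 day, strong increase beyond 7 days, ≈ 1 at 28 days) rather than
strict monotonicity across all five intervals. Second, the sensitivity
ranking at the 21-day interval is headed by CL, α, h_act, V and k_apop:
the ratio at 21 days is controlled by *when* the activation signal decays
below k_apop (the onset of naive-pool refill), which is a property of the
PK tail and the activation Hill shape. Parameters that scale both dose
windows' release nearly equally (k_in,naive, E_max,cyt, EC50_cyt) have
second-order effects on the ratio and rank lower.

## Pool-model comparator

The comparator implements the classic tolerance structure of a finite
releasable reservoir: drug stimulates first-order release out of a pool
(Emax Hill trigger on C_pla, flux proportional to pool content), the pool
refills toward baseline at rate k_rep, and released cytokine is eliminated
first-order. All pool-specific values are this package's own calibration
(none are published for this adaptation): pool size 300 pg/mL,
E_max,rel = 0.5/h, h = 2, EC50 = 1 µg/mL, and k_rep = 0.012/h chosen so
the 28-day ratio is ≈ 1 (0.984) while the 1-day ratio (0.145) is within a
factor two of the mechanistic model's (0.105). Both models share the
interval trend; they differ most around 14 days, where the pool refills
faster than the naive T-cell compartment.

## Synthetic observations

`generate_synthetic_observations` emulates the shape of the two-dose
in-vivo readout (one IL6 sample 2 h after each dose, five interval groups,
mean ± SEM): replicates are drawn multiplicative-lognormally around the
model's own 2 h prediction with CV 0.3 by default (cytokine levels are
positive and right-skewed; the original report shows only SEM bars), with
the lognormal location mean-corrected so replicates are unbiased. These
tables are synthetic stand-ins generated *from the model*; they exercise
the observed-versus-predicted machinery and file formats, and passing
those tests demonstrates internal consistency, not agreement with real
measurements. Any user CSV in the documented schema
(`group,dose_day,obs_time_h,il6_pg_ml,sem_pg_ml,n`) is analyzed
identically. Group size n defaults to 5 per group, a typical cohort size
for mouse PKPD studies.

## Problem sizes

Default simulations resolve 0.1 h steps over horizons of last-dose + 14
days (scenario battery), 35 days (single-dose dynamics) or 45 days
(recovery); the full battery is 5 two-dose simulations and the sensitivity
analysis 35 (17 parameters × 2 directions + baseline, minus the one-sided
I_max). All are exact model evaluations, not scaled-down approximations.

## Known limitations

- Cytokine release from monocytes/macrophages is not modeled; IL6 comes
  from T-cells only.
- Parameters are calibrated values from a single dose level; the
  exposure–activation relationship is not identified and assumes complete
  naive-pool transfer at 0.5 mg/kg.
- No parameter estimation or fitting machinery; no inter-individual
  variability; no unequal (step-up) dose optimization.
- The E:T-gated IL2 proliferation term is an empirical stand-in for
  several mechanisms (IL2 downregulation, regulatory T-cells) and was
  informed by in-vitro ratios.
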