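# Default parameters of the mechanistic TCE cytokine-release PKPD model
# (tumor-bearing mouse, anti-HER2 TCE).  Units: volumes mL, clearance mL/h,
# cell pools cells/uL, TCE concentration ug/mL, cytokine pg/mL, rates 1/h.
# The IL6 synthesis rate k_in_cyt is derived (10 pg/mL baseline * k_deg_cyt)
# and is therefore not listed here.

# pharmacokinetics
V: 2.3
CL: 0.025

# T-cell kinetics
k_in_naive: 16.0
k_apop: 0.01

# T-cell activation
Emax_act: 1.5
h_act: 2.0
EC50_act: 1.0
k_delay: 2.5

# cytokine (IL6) release
k_deg_cyt: 0.41
Emax_cyt: 0.00086
h_cyt: 2.5
EC50_cyt: 5.0
alpha: 2.0

# IL2-driven T-cell proliferation
k_IL2: 0.0008
I_max: 1.0
h_IL2: 5.0
EC50_ET_IL2: 7.0

# tumor kinetics and killing
k_g: 0.006
k_delay_tumor: 0.02
Emax_kill: 0.000025
EC50_kill: 1.0
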