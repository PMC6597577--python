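# Calibrated default parameters of the P-gp resistance kinetics model.
# Units: activity axis is normalized log-P-gp fluorescence on [0, 1];
# times in hours; drug concentrations in nM; MV concentrations in
# arbitrary units; cell counts in cells.
#
# basal activity centers and seed width (sensitive low mode, resistant high mode)
b1: 0.25
b2: 0.70
s_basal: 0.07
# maximal proliferation rates (1/h) and efflux-cost slope (dimensionless)
r_max_1: 0.035
r_max_2: 0.030
c_cost: 0.3
# carrying capacity of the culture well (cells)
K_cap: 2.0e6
# division-driven reversion toward basal: per-division fraction and
# daughter-activity dispersion
lambda_rev: 0.95
sigma_div: 0.07
# Lamarckian induction: amplitude (activity/h at saturating drug)
alpha_I: 0.03
# dose response: half-maximal concentration (nM) and Hill exponent
C50: 40.0
h_drug: 2.0
# therapy function: maximal kill rate (1/h), protection sigmoid midpoint/width
delta_max: 0.12
x_half: 0.45
w_prot: 0.06
# MV-mediated transfer velocity amplitudes (activity/h per MV unit),
# without / with drug; the with/without ratio is the ten-fold transfer contrast
kappa0: 2.0e-4
kappaD: 2.0e-3
# MV kinetics: shedding per resistant cell (MV units/cell/h), uptake per
# sensitive cell (1/cell/h), drug threshold for kappaD (nM), clearance (1/h)
gamma_shed: 5.0e-6
gamma_up: 1.0e-6
drug_transfer_threshold: 1.0
mv_clearance: 0.0
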