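# Manually tuned ("fiducial") starting parameter set of the hsrsim HSR model.
# Units: time s, concentrations mM, temperature K, energies J/mol.
k_TP = 3.5e-08
E_A = 350000.0
T_ref = 298.15
k_P = 9.938
k_S = 0.072
kp_S = 0.016
m = 2.4
P0 = 0.015
kp_F = 1.09
K_F = 0.042
k_F = 3.0
k_FaG = 50.0
kp_FaG = 0.021
k_FG = 5.0
kp_FG = 0.00032
pi_mF = 0.01
pi_mH = 0.01
pi_F = 3e-07
pi_H = 0.0043
eta_mF = 0.00045
eta_mH = 0.00085
eta_F = 3.3e-05
eta_H = 0.00015
total_P = 1.0
total_SK = 1.0
total_G = 1.0
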