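# Calibrated ("final") parameter set of the hsrsim HSR model.
# Units: time s, concentrations mM, temperature K, energies J/mol.
k_TP = 3.542e-08
E_A = 350000.0
T_ref = 298.15
k_P = 9.938
k_S = 0.07161
kp_S = 0.01626
m = 2.354
P0 = 0.01461
kp_F = 1.09
K_F = 0.04194
k_F = 2.976
k_FaG = 50.0
kp_FaG = 0.02124
k_FG = 5.0
kp_FG = 0.0003175
pi_mF = 0.01
pi_mH = 0.01
pi_F = 3.007e-07
pi_H = 0.004298
eta_mF = 0.0004545
eta_mH = 0.0008465
eta_F = 3.302e-05
eta_H = 0.0001529
total_P = 1.0
total_SK = 1.0
total_G = 1.0
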