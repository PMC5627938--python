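burn_in = 1000.0
depression_enabled = True
dt = 0.1
duration = 20000.0
feedback_enabled = True
lfp_gain = 1.0
mean_normalize_weights = True
mg = 0.25
n_weight_bins = 10
record_dt = 1.0
seed = 0
sigma_ln = 0.5
v_gaba = -70.0
v_hold = -27.0
exc.c = 0.7
exc.g_l = 0.034
exc.v_rest = -65.0
exc.v_reset = -40.0
exc.dt_ap = 1.5
exc.gamma = 2.85
exc.ell = 1.0
exc.tau_m0 = 14.4
exc.area = 0.0001
exc.v_k = -70.0
exc.v_m = -80.0
exc.g_dr = 0.76
exc.g_a = 4.36
exc.g_m = 0.4
exc.g_ahp = 0.3
exc.v_th_base = -40.0
exc.v_th_amp = 50.0
exc.v_th_tau = 10.0
exc.sigma_v0 = 2.0
exc.tau_noise = 4.0
exc.grid_b = 100.0
exc.grid_n = 100
inh.c = 1.0
inh.g_l = 0.1
inh.v_rest = -60.0
inh.v_reset = -40.0
inh.dt_ap = 1.4
inh.tau_m0 = 9.7
inh.area = 0.0001
inh.v_k = -80.0
inh.g_k = 40.0
inh.v_th_base = -50.0
inh.v_th_amp = 20.0
inh.v_th_tau = 10.0
inh.sigma_v0 = 3.0
inh.tau_noise = 4.0
inh.grid_b = 40.0
inh.grid_n = 50
depression.tau_glu = 2000.0
depression.tau_gaba = 2000.0
depression.u_glu = 0.04
depression.u_gaba = 0.04
gap.g_gj = 0.2
ou.sigma = 20.0
ou.tau = 4.0
ou.to_e = False
synapses.ampa_e.g_max = 0.6
synapses.ampa_e.tau_rise = 1.7
synapses.ampa_e.tau_decay = 8.3
synapses.nmda_e.g_max = 0.6
synapses.nmda_e.tau_rise = 6.7
synapses.nmda_e.tau_decay = 100.0
synapses.gaba_e.g_max = 0.5
synapses.gaba_e.tau_rise = 0.5
synapses.gaba_e.tau_decay = 20.0
synapses.ampa_i.g_max = 0.2
synapses.ampa_i.tau_rise = 1.7
synapses.ampa_i.tau_decay = 8.3
synapses.nmda_i.g_max = 0.2
synapses.nmda_i.tau_rise = 6.7
synapses.nmda_i.tau_decay = 100.0
synapses.gaba_i.g_max = 0.5
synapses.gaba_i.tau_rise = 0.5
synapses.gaba_i.tau_decay = 20.0
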