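# Default configuration: a 16 h HEK293-like cell cycle with CDK2 activity
# spanning G1/S and CDK1 activity in late G2/M, and NICD kinetics giving the
# unphosphorylated form a ~2 h half-life and the phosphorylated form a much
# shorter one.

[cell_cycle]
d_g1 = 7.0
d_s = 5.0
d_g2 = 3.0
d_m = 1.0
w2 = [7.0, 11.0]
w1 = [13.5, 15.5]
release_point = 6.5
dispersion = 0.5
ramp_width = 0.0

[kinetics]
alpha = 1.0
delta_n = 0.35
delta_p = 5.0
k1 = 4.0
k2 = 4.0
k_base = 0.2

[treatments]
inhibition = 0.95
duration = 3.0

[experiment]
n_cells = 1000
t_start = 0.0
t_stop = 12.0
t_step = 2.0

[clock]
n_oscillators = 200
period_ref = 130.0
beta = 0.5
n_periods = 20.0

[synth]
base_period = 90.0
wavefront_speed = 1.0
commitment_lag = 3
period_factor = 1.2
noise_cv = 0.1
n_somites = 8
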