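lv_emax: 2.1053
lv_emin: 0.099154
lv_v0: 5.0
la_e: 0.217763
la_v0: 14.0
rv_emax: 0.6
rv_emin: 0.045
rv_v0: 10.0
ra_e: 0.12
ra_v0: 10.0
tsys_k: 0.50954
mi_r: 0.0115
mi_l: 0.0006
ao_r: 0.01061
ao_l: 0.001577
ti_r: 0.007688
ti_l: 0.0019
po_r: 0.008
po_l: 0.0008
sa_c: 1.509
sa_v0: 500.0
sv_c: 30.16
sv_v0: 2800.0
pa_c: 3.8
pa_v0: 100.0
pv_c: 15.289
pv_v0: 300.0
r_sys: 1.3066
r_ven: 0.05
r_pul: 0.137664
r_pv: 0.006
total_volume: 4680.0
act_peak_frac: 0.62623
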