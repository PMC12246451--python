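# Focused single-side-band acquisition at 200 kV: 27.42 mrad probe,
# 0.15903 Å scan step, 192²-pixel detector covering 79.8 mrad.
method = "SSB"

[beam]
voltage_kv = 200.0
alpha_mrad = 27.42
defocus_nm = 0.0
current_pa = 11.0
d0_A = 0.8

[scan]
step_A = 0.15903
nx = 128
ny = 128
dwell_us = 50.0

[detector]
n_pixels = 192
pitch_um = 100.0
camera_length_cm = 12.030075187969924
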