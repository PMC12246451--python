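# Microscope calibration table (see ptychoplan.io for the schema).
[beam]
voltages_kv = [80.0, 200.0]

[apertures]  # aperture name -> convergence semi-angle (mrad)
"40um" = 27.42
"30um" = 20.52
"20um" = 13.52
"10um" = 6.02

[magnifications]  # magnification label -> field of view (Å)
"30M" = 80.0

[camera_lengths]  # nominal (cm) -> effective (cm)
"4" = 6.0
"8" = 12.030075187969924
"15" = 22.5
"30" = 45.0

[detector]
n_pixels = 192
pitch_um = 100.0
binnings = [1, 2, 4, 8, 24, 48]
paar_mrad = 100.0
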