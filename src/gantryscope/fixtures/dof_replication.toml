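# Wedge depth-of-field replication fixture.
#
# Optics for the wedge twin: a 0.5 mm focus band (half-width 0.25 mm) imaged
# at 0.05 mm layer spacing, so 10 of the 20 printed layers fall inside the
# band and the estimator reports DOF = 10 x 0.05 = 0.5 mm.

[optics]
pixel_pitch_sample_um = 6.45
dof_halfwidth_mm = 0.25
defocus_slope = 8.0
blur_sigma_in_focus_px = 1.0
vignette_strength = 0.05
radial_distortion_k1 = 0.0
noise_sd = 2.0
bit_depth = 8

[wedge]
layer_spacing_mm = 0.05
n_layers = 20
focus_fraction = 0.5
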