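# Treated critical defect: 8 mm gap, alginate hydrogel + 5 ug BMP-2,
# 12 weeks. All omitted keys keep the package defaults.

[scenario]
gap_mm = 8.0
gel_present = true
bmp2_dose_ug = 5.0
horizon_days = 84
mesh_h = 0.4

[load]
axial_load = 14.4          # N, peak axial gait load
fixator_stiffness = 277.0  # N/mm, external fixator

[rules]
psi_bone_max = 6e-3        # distortional strain bound of the osteogenic fate
psi_cartilage_max = 3e-2
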