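# Coarse end-to-end smoke configuration: 205 um fixed simulation grid and
# 125 um voxels (64 x 64 x 24 scaffold lattice), high-flow operating point.

seed = 7

[solver]
inlet_velocity = 0.061   # m/s, high-flow group
mode = "fixed"
grid_spacing = 205e-6    # m, commensurate with the 1.025 mm tube radius
include_inertia = true
tol = 1e-4

[synth]
voxel_size = 125e-6      # m -> 64 x 64 x 24 voxel scaffold lattice
porosity = 0.55
rate = 0.6
bonus = 0.35
weeks = [2, 3, 4, 5, 6]
psf_sigma = 0.5
noise_sd = 15.0
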