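"""Simulate a bead z-scan and fit every frame with a 2D Gaussian.

Builds a small calibration acquisition (11 z-steps of 100 nm, 2 frames per
step, 8 beads), localizes all spots, and shows how the fitted PSF width
grows away from the focal plane — the physical signal the virtual
light-sheet thresholds exploit.
"""

from vlsmlm import localize_stack, psf_sigma_at_z, simulate_bead_zstack, OpticsModel

stack = simulate_bead_zstack(
    n_beads=8, z_min=-500, z_max=500, z_step=100, frames_per_step=2, seed=1
)
print(f"simulated {stack.n_frames} frames of {stack.frame_shape} px, "
      f"{len(stack.truth)} beads")

locs = localize_stack(stack)
locs = locs[locs.fit_ok]
print(f"fitted {len(locs)} localizations")

optics = OpticsModel()
print("\n  z [nm]   mean fitted width [nm]   defocus law sigma(z) [nm]")
for z, group in locs.groupby("true_z_nm"):
    print(f"  {z:+6.0f}   {group['sigma_nm'].mean():20.1f}   "
          f"{psf_sigma_at_z(z, optics):23.1f}")
print("\nThe fitted width tracks sigma(z) = 175 sqrt(1 + (z/400)^2): "
      "out-of-focus emitters are wider (and dimmer), so width and "
      "amplitude thresholds can carve out a thin axial slab.")
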