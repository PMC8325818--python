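"""Discover an expression gradient de novo, then profile genes along it.

The fixture concentrates one gene around x = 500 while another is uniform;
the gradient field localizes the variation, and a supervised projection
onto the left edge recovers the 1D expression profiles.
"""

import numpy as np

import spotmap
from spotmap import simulate as sim

spec = sim.TissueSpec(
    gradient_genes={"Rorb": 80.0},
    reads_per_gradient_gene=6000,
    background_genes=["Slc17a7"],
    reads_per_background_gene=3000,
)
spots, _ = sim.make_layered_tissue(spec, seed=2)

gf = spotmap.gradient_field(spots, ["Rorb"], bandwidth=60)
iy, ix = np.unravel_index(np.argmax(gf.g_x), gf.g_x.shape)
print(f"G_x peaks at x = {gf.lattice_x[ix]:.0f} px "
      f"(flank of the Rorb bump generated at x = 500 ± 80)")
print(f"interior max G_y / max G_x = "
      f"{gf.g_y[~gf.boundary_mask].max() / gf.g_x.max():.3f} "
      f"(no planted y-variation; residual is sampling noise)")

# supervised: project every read onto its distance from the left edge
origin = np.column_stack([np.zeros(50), np.linspace(0, 1000, 50)])
proj = spotmap.project_to_axis(spots, origin)
profiles = spotmap.axis_profiles(proj)
for gene, (grid, dens) in profiles.items():
    mode = grid[np.argmax(dens)]
    print(f"{gene}: 1D profile mode at d = {mode:.0f} px")
# Rorb's profile peaks near d = 500 (its planted center); the uniform gene
# is flat, so its mode is uninformative
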