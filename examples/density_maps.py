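"""Density-map arithmetic: half-map FSC resolution and difference blobs.

Renders a toy dodecamer at 10 A resolution, makes two half-maps with
independent noise, and reports the gold-standard FSC = 0.143
resolution.  Then inserts six Gaussian blobs (standing in for
unmodelled density such as flexible arms) and recovers them from the
standardized difference map.
"""

import numpy as np

from oligoxl import density, synthetic

assembly, _, _ = synthetic.make_assembly_fixture(30.0, 35.0, seed=1,
                                                 n_residues=15)
coords = assembly.ca_coords()

base, half1, half2, _ = synthetic.make_map_fixture(
    coords, resolution=10.0, voxel=2.5, noise_sd=0.8, seed=2)
fsc = density.fsc(half1, half2)
res = density.resolution_at(fsc, threshold=0.143)
print(f"rendered at 10.0 A; half-map FSC 0.143 resolution: {res:.1f} A")

with_blobs, _, _, truth = synthetic.make_map_fixture(
    coords, resolution=10.0, voxel=2.5, n_blobs=6, seed=3)
diff = density.difference_map(with_blobs, base)
blobs = density.count_blobs(diff, level=0.5 * diff.values.max())
print(f"difference map: {len(blobs)} positive blobs "
      f"({truth.params['n_blobs']} inserted)")
for b, c in zip(blobs, np.asarray(truth.params["blob_centres"])):
    print(f"  blob of {b['voxels']} voxels at "
          f"({b['centroid'][0]:.0f}, {b['centroid'][1]:.0f}, "
          f"{b['centroid'][2]:.0f}) A")
# Positive difference density localizes exactly where density was added
# on top of the base model -- the same logic that locates unmodelled
# arms in an experimental map.
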