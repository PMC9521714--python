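"""Detect high-density regions in a synthetic synapse localization field.

Builds a two-channel SMLM field (scaffold-marker disc + clustered target
channel), scores the target channel against a uniform-randomization
density null, links supra-cutoff localizations into HDRs, outlines the PSD
from the marker channel, and classifies each HDR's position.
"""

import numpy as np

import spinenano as sn

params = sn.SmlmSimParams(seed=42)
psd_field, target_field, truth = sn.gen_smlm_synapse(params)

density = sn.randomization_null(target_field, radius=50.0, n_reps=100, seed=1)
hdrs = sn.delineate_hdrs(target_field, density)
outline = sn.delineate_psd(psd_field, seed=2)
hdrs = sn.classify_hdr_positions(hdrs, outline)

print(f"density cutoff: {density.cutoff:.1f} neighbors within 50 nm "
      f"(null {density.null_mean:.1f} +/- {density.null_sd:.1f})")
print(f"{len(hdrs)} HDRs found ({params.n_hdrs} planted):")
for h in hdrs:
    err = np.min(np.hypot(*(truth["hdr_centroids"] - np.array(h.centroid)).T))
    print(f"  {h.n_points:4d} localizations, diameter {h.diameter:5.0f} nm, "
          f"{h.position_class:>15s}, centroid error {err:4.1f} nm")
# Diameters near 100-300 nm and a peri-synaptic majority are the expected
# nanodomain geometry; the cutoff is mean + 2.5 SD of the uniformized field.
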