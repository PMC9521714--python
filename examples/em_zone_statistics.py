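"""Zone-resolved immunogold distance statistics on a synthetic spine.

Generates an annotated spine cross-section with gold particles placed at
the wild-type zone offset models (synaptic 34 +/- 18 nm, extrasynaptic
13 +/- 5 nm; 180 vs 309 labels), then recovers zones, membrane-distance
summaries, and the zone label fractions.
"""

import spinenano as sn

annotation, truth = sn.gen_em_spine(sn.EmSimParams(seed=7))
table = sn.zone_table(annotation, depth=100.0)

counts = {}
for _, zone, _ in table:
    counts[zone] = counts.get(zone, 0) + 1
fractions = sn.zone_label_fractions(
    {z: counts[z] for z in ("synaptic", "extrasynaptic")}
)

for zone in ("synaptic", "extrasynaptic"):
    d = [dd for _, z, dd in table if z == zone]
    s = sn.summarize_distances(d)
    print(f"{zone:>13s}: n={s.n:3d}  {s.mean:5.1f} +/- {s.sd:4.1f} nm  "
          f"CV={s.cv:.2f}  {fractions[zone]['percent']}% of labels")

# Nearest-neighbor spacing is a per-spine quantity: one annotated spine
# carries a handful of labels, not the pooled cohort totals above.
sparse, _ = sn.gen_em_spine(
    sn.EmSimParams(seed=8, zone_counts={"synaptic": 4, "extrasynaptic": 9})
)
nnd = sn.nearest_neighbor_distances(sparse.particle_xy())
print(f"per-spine nearest-neighbor distance: mean {nnd.mean():.0f} nm, "
      f"min {nnd.min():.0f} nm (n={len(nnd)})")
# The synaptic zone mean sits tens of nm under the membrane (label under
# the PSD lattice) while extrasynaptic labels hug the membrane; the 37/63
# percent split matches the generated label counts.
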