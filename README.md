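# spinenano

Quantitative analysis of the nanoscale organization and mobility of
postsynaptic scaffold proteins (the AKAP79/150 family and similar
membrane-associated scaffolds) in dendritic spines. The package implements
three bespoke analyses used to characterize how palmitoylation shapes a
scaffold's distribution at the synapse, each paired with a seeded
synthetic-data generator so that every stage can be exercised and scored
against known ground truth without any microscopy data:

1. **SMLM high-density regions** (`spinenano.smlm`) — coordinate-based
   cluster analysis of single-molecule localization maps. For each
   localization the neighbor count within radius *r* (default 50 nm) is
   compared with a null obtained by re-drawing the same number of points
   uniformly over the synaptic region; localizations above
   `null_mean + 2.5 · null_SD` are linked into high-density regions
   (HDRs), sized by the area-equivalent circle of their hull, and
   classified as PSD-overlapping / peri-synaptic / distal against a
   density-based outline of the postsynaptic density (PSD).
2. **Immunogold EM geometry** (`spinenano.emgeom`) — particle-to-membrane
   distances on annotated 2D spine contours, zone assignment (synaptic =
   within 100 nm beneath the PSD arc; extrasynaptic = within 100 nm of
   non-PSD spine membrane; deeper = cytoplasm), nearest-neighbor
   distances, single-linkage gold-cluster detection, distance summaries
   with CV, zone label fractions, per-spine endosome label fractions,
   rank/ANOVA group comparisons, and an N- vs C-terminus conformation
   classifier (vertical-extended vs parallel-or-compact).
3. **Single-molecule tracking** (`spinenano.tracking`) — pooled single-step
   displacement (jump) statistics at Δτ = 0.022 s and a ≤ 3-state diffusion
   hidden Markov model. Emissions in state *k* are zero-mean 2D Gaussian
   displacements with per-coordinate variance 2·D_k·Δτ (jump magnitudes are
   Rayleigh mixtures with ⟨r²⟩ = 4·D_k·Δτ); the model is fit by
   expectation-maximization with per-track forward–backward passes, the
   state count selected by BIC, and the fit reports diffusion coefficients
   D, the per-step transition matrix A, stationary occupancies π, and mean
   dwell times Δτ/(1 − A_kk).

`spinenano.synthgen` provides the generators (localization fields with
planted Gaussian nanoclusters, annotated spine cross-sections with
truncated-normal membrane offsets per zone, switching-state Brownian
trajectories with geometric photobleaching-limited lengths) plus reference
wild-type and palmitoylation-deficient (CS) three-state mobility models.
`spinenano.io` reads and writes the CSV/JSON formats (ThunderSTORM-style
localization tables accepted), and `spinenano.pipeline` / the `spinenano`
CLI orchestrate multi-stage runs.

## Worked example

```sh
python examples/single_molecule_hmm.py
```

generates 3000 trajectories from the wild-type reference model and refits
them:

```
selected K = 3 states (BIC -70695), 17706 jumps, converged = True
 state    D fit   D true  pi fit  pi true  dwell s
     1    0.020    0.020   0.098    0.109    0.169
     2    0.120    0.120   0.633    0.614    0.119
     3    0.467    0.470   0.269    0.277    0.052
```

State 1 (lowest D) is the bound/immobile scaffold pool — short dwell
(~0.15 s) and D ≈ 0.02 μm²/s — while states 2–3 are the slow and fast
mobile pools; BIC recovers the planted three-state structure and the
diffusion coefficients within a few percent. The other examples print HDR
detection on a planted-cluster field (`examples/hdr_detection.py`:
3/3 clusters found, diameters 174–193 nm, peri-synaptic), zone-resolved
immunogold statistics (`examples/em_zone_statistics.py`: synaptic
35.8 ± 16.6 nm vs extrasynaptic 13.1 ± 4.5 nm, 37%/63% label split), and
jump-length statistics for both mobility models
(`examples/jump_statistics.py`: WT median 0.092 μm with 12% of jumps
≥ 0.2 μm; CS right-shifted with 47% short jumps).

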