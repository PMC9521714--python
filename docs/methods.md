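# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of the three analysis families and their synthetic
generators. Units are nanometres for localization/EM geometry, micrometres
and seconds for tracking.

## SMLM high-density-region analysis

**Model.** A localization field is a set of 2D molecular positions inside
an analysis region (ROI). Local density is the number of other
localizations within a fixed radius *r* of each localization (boundary
inclusive, self excluded). The null model is complete spatial randomness
at the observed intensity: each of `n_reps` replicates re-draws the same
number of points uniformly over the ROI polygon and scores them with the
same counting rule. The cutoff is `null_mean + m · null_SD` pooled across
replicates. Localizations strictly above the cutoff are single-linkage
linked at `link_radius`; components with at least `min_points` members are
HDRs. An HDR's effective diameter is that of the circle with the area of
the members' convex hull (degenerate collinear hulls fall back to the
maximum span). The PSD outline applies the same construction to the
scaffold-marker channel at multiplier `density_sd_cutoff` and returns a
concave hull of the largest supra-cutoff component. HDR centroids are
classified `psd-overlapping` (inside the outline), `peri-synaptic`
(within `peri_band` of its boundary), or `distal`.

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| density radius *r* | 50 nm | half the ~100 nm nanodomain scale; resolves 100–300 nm clusters without washing them out |
| cutoff multiplier *m* | 2.5 | the standard randomization-null threshold for this analysis |
| `n_reps` | 100 | null mean/SD stable to ~1%; seed mandatory |
| `link_radius` | = *r* | supra-cutoff points closer than the density scale belong to one region |
| `min_points` | 10 | suppresses chance chains of supra-cutoff points in uniform fields |
| `peri_band` | 100 nm | matches the peri-synaptic annulus used for zone definitions |
| PSD multiplier | 2.0 | the marker channel is dominated by the PSD itself; a softer threshold keeps the full disc |

The randomization region is the field's ROI; when no ROI is supplied the
convex hull of the localizations is used and logged. Counts carry no edge
correction: data and null are scored identically, so the edge bias cancels
in the comparison. Repeated localizations of one emitter (blinking) are
not corrected; the cutoff is therefore calibrated against the blink-
inflated intensity, which is conservative for cluster detection but means
absolute densities should not be read off the counts.

**Design choices.** Fixed-radius counting was chosen over k-nearest-
neighbor or kernel density estimates: it matches the randomization-null
construction exactly and has one interpretable scale parameter. The null
is computed per field, not pooled across fields, so each synapse is scored
against its own intensity. The PSD outline uses the channel's own
randomization null (the same construction as the HDR cutoff): a cutoff
placed relative to the raw count distribution of a channel dominated by
the dense PSD disc would sit above the disc's own counts and delineate
nothing.

## Immunogold EM geometry

**Model.** A spine annotation is a closed membrane contour (polyline, no
self-intersection), an optional PSD segment given as a contiguous vertex
arc, gold particle coordinates, and organelle records. Distance to the
membrane is the minimum point-to-segment distance to the contour. Zones:
a particle inside the contour is `synaptic` when its nearest contour
point lies on the PSD arc and the distance is ≤ 100 nm; `extrasynaptic`
when the nearest point is off the arc (spine annotations);
`nonsynaptic-shaft` analogously for dendrite-shaft annotations;
`cytoplasm` beyond 100 nm; `outside` otherwise. The "vertical distance"
of the zone definition is implemented as the minimum distance to the
contour, which coincides with perpendicular distance wherever the
membrane is locally flat; the nearest-point-on-arc rule bounds the PSD's
lateral extent without outward extrapolation of its edges. All geometry
is 2D (image plane / projection); 3D particle positions are out of scope.

Summary statistics use the n−1 SD, linear-interpolation quantiles, and
CV = SD/mean. Report-table percentages round half-up at printed
precision with the raw value retained. Gold clusters are single-linkage
components at 60 nm (about twice the ~30 nm minimum nearest-neighbor
spacing observed for scaffold labels) with ≥ 4 members; cluster diameter
is the maximum pairwise member distance. Group comparisons are two-sided:
Mann-Whitney (exact where possible) for two groups; Kruskal-Wallis with
Bonferroni-adjusted pairwise rank-sum as the nonparametric multi-group
path (a Dunn-type post-hoc; Bonferroni is the adjustment available in the
stack and is slightly conservative); one-way ANOVA with Tukey HSD as the
parametric path. No correction is applied across separate families of
comparisons.

The conformation classifier takes (mean, SD, n) membrane-distance
summaries for N- and C-terminus labels: `vertical-extended` when
mean_C/mean_N ≥ 1.5 and a Welch test on the summaries gives p < 0.01;
`parallel-or-compact` when the means are within 25% of each other or
p ≥ 0.05; `indeterminate` otherwise. The 1.5 ratio gate encodes
"one terminus about twice as deep as the other" with margin; the Welch
gate stops small-n noise from producing a vertical call.

**Label-position caveat.** Immunogold labels sit 10–20 nm from the
epitope (antibody bridge plus silver enhancement); distances are to the
particle centers as annotated and are not corrected for this offset.

## Single-molecule tracking

**Model.** Tracks are gapless trajectories at fixed Δτ (0.022 s);
gapped tracks are split at load, never interpolated; minimum length 2
positions. Jumps are Euclidean consecutive-frame displacements pooled
across tracks. Under a K-state model the per-step hidden state evolves by
a Markov matrix A and the displacement in state k is zero-mean bivariate
Gaussian with per-coordinate variance 2·D_k·Δτ; jump magnitudes follow the
Rayleigh mixture CDF Σ_k π_k (1 − exp(−r²/(4 D_k Δτ + 4 σ_loc²))), which
the package exposes in closed form as an independent oracle for the
simulated statistics.

**Fitting.** Maximum-likelihood expectation-maximization with scaled
per-track forward–backward passes, batched over tracks. The M-step is
closed-form (D_k from posterior-weighted mean squared jumps; A from
pairwise expectations; a free shared initial distribution). Localization
error is not included in the default emission variance, mirroring the
variational displacement-HMM approach this estimator replaces; an
additive 4σ² term is available in the mixture oracle and the generator.
Model selection fits K = 1..3 and picks the smallest BIC
(−2·loglik + p·ln n_jumps with p = K + K(K−1) + (K−1)); the hard K ≤ 3
cap guards against over-fitting the short-track regime. States are
relabeled by ascending D, so state 1 is bound/immobile; reported
occupancies are the stationary distribution of the fitted A; dwell times
are Δτ/(1 − A_kk). Initialization: log-spaced D seeds over
[0.05, 5] × the empirical mean-squared-displacement scale with
log-normal perturbation per restart, diagonal-0.8 transition start,
10 restarts, relative log-likelihood tolerance 1e-8, 1000 iterations
maximum; non-convergence is returned flagged, and the per-iteration
log-likelihood trace is kept so ascent can be asserted. Fits require
≥ 100 pooled jumps. Tracks are pooled across ROIs/cells; per-ROI fitting
is a matter of passing the subset.

**Reference mobility models.** The wild-type model is D = 0.02/0.12/0.47
μm²/s with occupancies 0.11/0.62/0.28 (printed values summing to 1.01,
renormalized); the palmitoylation-deficient (CS) model is
D = 0.02/0.15/0.52 μm²/s with occupancies 0.11/0.55/0.34, the bound-state
D shared with wild type since the per-state coefficients are essentially
construct-independent. Only three off-diagonal transition entries per
construct are known (bound→slow 0.10/0.24, bound→fast 0.05, fast→slow
0.39/0.27 per 22 ms step); the remaining entries are closed by detailed
balance against the occupancies (π_i A_ij = π_j A_ji), a construction of
this package — adequate for simulation since it preserves the stationary
occupancies, the bound-state escape rate, and the marginal jump
distribution, but not asserted to be the experimentally fitted matrix.
`build_transition_matrix` exposes the same construction for arbitrary
(π, stay) inputs, solving the symmetric flow system; infeasible
combinations (negative flows) are rejected.

## Synthetic generators

All generators take a mandatory seed (identical seeds ⇒ bit-identical
output) and return ground truth sufficient to score recovery.

**Localization fields** emulate a two-channel synapse: a marker channel
uniform in a PSD disc (radius 150 nm — the sub-500 nm PSD scale — at
5000/μm², the dense-lattice regime) and a target channel of uniform
background (200/μm²) plus isotropic Gaussian clusters (σ 40 nm,
200 points — the 100–200 nm nanodomain scale at realistic labeling
density). Peripheral placement rings cluster centers 5–95 nm outside the
disc boundary at evenly spaced angles with jitter; uniform placement
keeps centers 3σ inside the ROI and ≥ 5σ apart, so each truth centroid
marks one resolvable cluster. Every localization gets Gaussian jitter at
the 10 nm localization uncertainty; a blink factor > 1 adds
Poisson-distributed repeated localizations per emitter (default off).
Not emulated: detector pixelation, drift, channel misregistration,
emitter-density-dependent mislocalization — passing recovery tests shows
the coordinate analysis is correct, not that upstream image processing
is.

**Spine annotations** use a 500 × 400 nm elliptical head contour
(256 vertices) with a 300 nm PSD arc centered on top. Particles are
placed by drawing a lateral arc position uniformly within the zone's
membrane stretch (2 nm inside the arc boundaries, so truth zones are
never knife-edge ambiguous under contour discretization) and stepping
inward along the membrane normal by a truncated-normal offset — defaults
are the wild-type zone models, synaptic 34 ± 18 nm and extrasynaptic
13 ± 5 nm truncated to [0, 100] nm, with 180:309 labels. Organelle
records carry Bernoulli labeled flags (7 structures at 0.86 by default).
Not emulated: non-convex spine shapes, 3D tilt projection effects,
antibody displacement.

**Trajectories** draw the initial state from the stationary distribution
of A, evolve it per step, add Gaussian steps at variance 2·D·Δτ per
coordinate, and optionally add static localization error and reflection
at a confining disc (off by default). Track lengths are geometric with
mean 6 steps, mimicking photobleaching-limited track survival; the
pooled jumps-per-track ratio of the reference experiments (~5.4) sits
near this choice. Blinking-induced track splitting is not emulated
beyond the short-length law itself.

## Problem sizes

Stochastic checks use sizes at which the tested property is decisive:
jump-statistic checks pool ~1.5 × 10⁵ jumps (quantile SE < 0.001 μm);
HMM recovery uses 3000 tracks (~18k jumps), where the three states are
identifiable and D recovers within a few percent; detector
specificity/sensitivity use 100 uniform fields and 30 planted-cluster
fields (90 clusters). The acceptance script simulates 30 000 tracks per
model (~1.8 × 10⁵ jumps).

## Known limitations

- No blink/overcounting correction anywhere; HDR member counts and
  densities are label-level, not molecule-level.
- The extrasynaptic "vertical distance" is a minimum distance; for
  strongly curved membrane stretches it can undercut a strict
  along-the-PSD-normal reading.
- The EM fit's BIC can prefer fewer states when diffusion coefficients
  are close relative to 1/√n; the K ≤ 3 cap is a modeling choice, not a
  statement that more states are absent.
- Group comparisons assume independent observations; per-synapse
  clustering of particles is not modeled in the test statistics.
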