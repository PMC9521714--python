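"""Jump-length statistics of the two reference mobility models.

Simulates trajectories from the wild-type and palmitoylation-null (CS)
three-state models and compares the pooled single-step displacement
statistics with the closed-form Rayleigh-mixture quantiles.
"""

import spinenano as sn

for name, model in (("WT", sn.wt_reference_model()),
                    ("CS", sn.cs_reference_model())):
    params = sn.TrackSimParams(seed=5, D=model["D"], A=model["A"],
                               n_tracks=20000)
    tracks, _ = sn.gen_tracks(params)
    s = sn.jump_stats(sn.compute_jumps(tracks))
    med = sn.mixture_quantile(0.5, model["D"], model["pi"], model["dt"])
    print(f"{name}: median {s.median:.3f} um (closed form {med:.3f}), "
          f"25-75% {s.p25:.2f}-{s.p75:.2f} um, "
          f"<0.1 um: {100 * s.frac_short:.0f}%, "
          f">=0.2 um: {100 * s.frac_long:.0f}%")
# WT: median ~0.09 um with ~12% of jumps >= 0.2 um; the CS distribution is
# right-shifted (fewer short jumps), reflecting greater mobility.
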