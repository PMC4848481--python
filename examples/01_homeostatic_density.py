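"""Homeostatic density on a circular micropattern.

Generates a wild-type growth time course on an 800-um disc, measures the
time-resolved global density, and reports the late-time plateau -- the
homeostatic density the monolayer maintains by balancing division, death
and extrusion (the wild-type preset is 61 cells per 10,000 um^2).
"""

from mechcomp import competition, density, synthetic

cs = synthetic.make_count_timecourse(None, "homeostasis", seed=1)
tc = density.density_timecourse(cs.counts["cell"], cs.area_um2)
late = tc["density"][cs.time_h > 0.75 * cs.time_h[-1]]

growth = competition.growth_stats(cs)
late_rate = growth[growth["t_mid_h"] > 100.0]["rate_per_h"].mean()

print(f"frames: {len(cs.time_h)}, field area: {cs.area_um2[0]:.0f} um^2")
print(f"plateau density: {late.mean():.1f} cells per 10,000 um^2")
print(f"late-time growth rate: {late_rate:+.4f} log2-doublings/h")
# The plateau sits at the preset homeostatic density (61 +/- counting
# noise) and the late growth rate is ~0: the monolayer is in homeostasis.
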