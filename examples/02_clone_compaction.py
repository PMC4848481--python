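"""Compaction of a surrounded loser clone.

Builds a competition scene (a loser clone enclosed by winners), measures
the global density inside the clone and in a pure loser culture, and
classifies the clone's surround status.  Compacted surrounded clones are
several-fold denser than pure loser cultures (preset: 4.5-fold).
"""

import math

from mechcomp import competition, density, synthetic

cfg = synthetic.load_preset("competition_scene")
scene = synthetic.make_competition_scene(cfg, seed=2)

clone_area = math.pi * cfg["clone_radius"] ** 2
n_clone = int((scene.population == "loser").sum())
clone = density.global_density(n_clone, clone_area)

pure_cfg = synthetic.load_preset("pure_loser")
pure = density.global_density(
    synthetic.make_monolayer(
        synthetic.geometry_from_config(pure_cfg["geometry"]),
        pure_cfg["target_density"],
        pure_cfg["min_spacing"],
        seed=3,
    )
)

status = competition.classify_clone(scene, "loser", contact_radius_um=25.0)
print(f"clone: {n_clone} cells, {clone.density:.1f} per 10^4 um^2 ({status.status})")
print(f"pure loser culture: {pure.density:.1f} per 10^4 um^2")
print(f"compaction ratio: {clone.density / pure.density:.2f}-fold")
# A ratio near 4.5 means the surrounded clone is compacted far above the
# density the losers would ever reach on their own.
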