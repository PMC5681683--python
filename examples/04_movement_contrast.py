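"""Contrast movement on forays with intra-territorial movement.

Computes the proportion of fixes in water and the hourly travel speed per
movement type.  Intra-territorial speed uses only consecutive water-water
fix pairs (the conservative convention: the animals travel faster in
water); foray speed uses all pairs because forays yield few positions.
"""

import numpy as np

from foraykit import ForayParams, SimulationConfig
from foraykit.forays import classify_fixes
from foraykit.movement import classify_medium, proportion_in_water, travel_speed
from foraykit.simulate import simulate_population

config = SimulationConfig(
    seed=7, n_territories=6, territory_length_km=2.5, n_nights=12,
    foray=ForayParams(p_per_night=0.3, p_never=0.0),
)
bundle = simulate_population(
    config, statuses=[(f"B{i:02d}", "dominant") for i in range(1, 7)]
)

rows = []
for (iid, _), home in bundle.home_map.items():
    fx = bundle.fixes[bundle.fixes["individual_id"] == iid].reset_index(drop=True)
    fx["movement_type"] = classify_fixes(
        fx, bundle.landscape.territories[home],
        bundle.landscape.neighbor_territories(home),
    )
    fx["medium"] = classify_medium(fx, bundle.landscape.water)
    for mt, media in (("intra", "water_only"), ("foray", "all")):
        sub = fx[fx["movement_type"] == mt]
        if len(sub) == 0:
            continue
        speeds = [r.speed_m_per_hr for r in travel_speed(fx, mt, media_used=media)]
        rows.append((mt, proportion_in_water(sub), speeds))

for mt in ("intra", "foray"):
    props = [p for m, p, _ in rows if m == mt]
    speeds = np.concatenate([s for m, _, s in rows if m == mt and s])
    print(f"{mt:6s}: proportion in water {np.mean(props):.2f}, "
          f"hourly speed {np.mean(speeds):.0f} m/hr (n={len(speeds)} hours)")
# Forays should come out faster and wetter than intra-territorial movement:
# excursions are direct swims along the river, while within-territory
# movement mixes foraging bouts on land.
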