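"""Word survival times: a few long-lived words atop many ephemeral ones.

Runs the Star fixture and summarizes how long each transient word lived
(birth to death, in steps; the shared initial word and words still alive at
the end are excluded).
"""

import numpy as np

from dialectsim import fixture_topology, run_simulation, survival_times

topo, params = fixture_topology("star")
result = run_simulation(topo, params.with_overrides(seed=12))
lives = np.array(survival_times(result.registries))

print(f"{len(lives)} words were born and died within {params.T} steps")
print(f"median survival: {np.median(lives):.0f} steps")
print(f"mean survival:   {lives.mean():.1f} steps")
print(f"90th percentile: {np.percentile(lives, 90):.0f} steps")
print(f"longest-lived:   {lives.max()} steps")
print("\nThe mean exceeding the median shows the right skew: most innovations")
print("are immediately displaced by established words, while a small number")
print("ride the centre's influence and persist vastly longer.")
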