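"""Standard testing environments and boundary-distance queries.

Builds the five standard arenas, inserts the 50 x 3 cm barrier into the
walled square, and casts allocentric rays.  The printed distances are what a
boundary vector cell's receptive field "sees" from a given position.
"""

import math

import boundarycell as bc

for name in ("walled_circle", "walled_square", "unwalled_circle", "together", "apart"):
    env = bc.make_standard_environment(name)
    kinds = {el.kind for el in env.elements}
    print(f"{name:15s} {len(env.elements):3d} boundary elements ({', '.join(sorted(kinds))})")

square = bc.make_standard_environment("walled_square")
env_b = bc.insert_barrier(square, centre=(0, 0), orientation=0.0)  # east-west

print("\nDistances from (0, 10) cm in the walled square with a central barrier:")
for label, direction in [("east", 0.0), ("north", math.pi / 2), ("south", -math.pi / 2)]:
    d = bc.boundary_distance(env_b, (0, 10), direction)
    print(f"  looking {label:5s}: first boundary at {d:5.1f} cm")
print("(southward the ray stops at the barrier's north face at y = 1.5 cm,")
print(" so the nearest southern boundary is 8.5 cm away, not the 60 cm wall)")
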