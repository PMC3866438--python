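"""Barrier-elicited field repetition: the BVC classification criterion.

A cell firing along the south wall is predicted, if it is a BVC, to fire
along the *north* side of a barrier inserted perpendicular to its preferred
direction — positions just north of the barrier now also have a proximal
boundary to the south.  The criterion: at least 40% of the locational peak
rate in at least 50% of the bins abutting the predicted side.
"""

import math

import boundarycell as bc

env = bc.make_standard_environment("walled_circle")
params = bc.BVCParams(d_pref=8.0, phi_pref=-math.pi / 2)

# baseline trial
traj = bc.simulate_trajectory(env, duration=1620.0, seed=42)
spikes = bc.generate_spikes(bc.bvc_rate_field(params, env).as_rate_fn(), traj, seed=7)
baseline = bc.compute_rate_map(bc.filter_positions(traj), spikes)

# barrier trial: barrier perpendicular to the cell's preferred direction
env_b = bc.insert_barrier(env, centre=(0, 0), orientation=params.phi_pref + math.pi / 2)
traj_b = bc.simulate_trajectory(env_b, duration=1620.0, seed=43)
spikes_b = bc.generate_spikes(bc.bvc_rate_field(params, env_b).as_rate_fn(), traj_b, seed=8)
barrier = bc.compute_rate_map(bc.filter_positions(traj_b), spikes_b)

result = bc.classify_bvc(baseline, barrier, env, env_b)
print(f"eligible (field at/near perimeter): {result.eligible}")
print(f"inferred preferred direction: {math.degrees(result.side.phi_pref):.0f} deg "
      f"(truth: {math.degrees(params.phi_pref):.0f} deg)")
print(f"predicted side: {result.side.label}")
cov = result.coverage
print(f"coverage: {cov.n_above}/{cov.n_abutting} abutting bins >= "
      f"{cov.threshold_rate:.2f} Hz -> {cov.coverage:.0f}%")
print(f"classified as BVC: {result.is_bvc}")
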