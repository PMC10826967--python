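"""Intrinsic firing patterns: pseudo-plateau bursting vs tonic spiking.

Simulates one uncoupled lactotroph with the default (burster) parameters
and one with the BK conductance removed (spiker), classifies the voltage
events, and compares calcium and secretion.
"""

import collections

import pitnet as pn
from pitnet import events as ev

cfg = pn.SimConfig(dt=0.5, t_end=60_000, t_transient=20_000, g_c=0.0, seed=1)

for name, params in [("burster", pn.burster_params()), ("spiker", pn.spiker_params())]:
    traj = pn.run_single_cell(params, cfg)
    train = ev.event_train(traj, 0)
    w = traj.window()
    print(f"{name} (g_BK = {params.g_bk} nS):")
    print(f"  events over 40 s: {dict(collections.Counter(train.labels))}")
    print(f"  mean Ca2+  <c> = {w.c.mean():.4f} uM")
    print(f"  mean secretion <s> = {w.s.mean():.4f}")

print(
    "\nThe burster's longer depolarized events accumulate more Ca2+, and the"
    "\nsteep secretion sigmoid amplifies that difference: bursting cells are"
    "\nthe secreting cells, spiking cells secrete little."
)
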