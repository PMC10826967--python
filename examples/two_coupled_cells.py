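"""A burster converts a spiker to bursting when coupling is strong enough.

Couples one intrinsic burster to one intrinsic spiker through a gap
junction at weak (0.005 nS) and stronger (0.05 nS) conductance and
reports conversion, synchrony, and secretion.
"""

import collections

import pitnet as pn
from pitnet import events as ev
from pitnet.netgen import CellNetwork

net = CellNetwork(2, frozenset({(0, 1)}), types=("burster", "spiker"))

for g_c in (0.005, 0.05):
    cfg = pn.SimConfig(dt=0.5, t_end=60_000, t_transient=20_000, g_c=g_c, seed=1)
    traj = pn.run_network(net, None, cfg)
    w = traj.window()
    train = ev.event_train(traj, 1)
    converted, frac = ev.is_converted_burster(train)
    sync = ev.synchrony_index(traj)
    print(f"g_c = {g_c} nS:")
    print(f"  spiker events: {dict(collections.Counter(train.labels))}")
    print(f"  spiker converted to bursting: {converted} (burst fraction {frac:.2f})")
    print(f"  synchrony index (Ca2+ correlation): {sync:.3f}")
    print(f"  total secretion s_burster + s_spiker = "
          f"{w.s[0].mean() + w.s[1].mean():.4f}")

print(
    "\nWeak coupling leaves the spiker spiking with persistent phase drift;"
    "\nat ten times the conductance the cells synchronize, the spiker emits"
    "\n2-spike bursts, and the pair's total secretion rises."
)
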