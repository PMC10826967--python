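"""Random-walk cell networks, placement strategies, and homophily.

Grows a 20-cell structural network, places 50% intrinsic bursters by
each strategy, and reports the burster homophily Gamma_b each achieves.
Also demonstrates the TSV round trip.
"""

import tempfile
from pathlib import Path

import pitnet as pn

net = pn.random_walk_network(pn.GenConfig(n=20, p=0.7, seed=42))
print(f"structural network: {net.n_nodes} cells, {net.n_edges} gap junctions")
degs = [net.degree(v) for v in range(net.n_nodes)]
print(f"degrees: min {min(degs)}, max {max(degs)}")

for strategy in ("offensive", "random", "defensive"):
    cfg = pn.GenConfig(n=20, seed=5, burster_fraction=0.5, placement=strategy)
    lab = pn.assign_types(net, cfg)
    rep = pn.homophily(lab)
    print(f"{strategy:>9}: bursters {sorted(lab.burster_ids())} "
          f"Gamma_b = {rep.Gamma_b:.3f}, Gamma_s = {rep.Gamma_s:.3f}")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "network.tsv"
    lab = pn.assign_types(net, pn.GenConfig(n=20, seed=5, burster_fraction=0.5))
    pn.write_network_tsv(lab, path)
    assert pn.read_network_tsv(path) == lab
    print(f"\nTSV round trip OK ({path.name}, {path.stat().st_size} bytes)")

print(
    "\nGamma_b near 0 disperses bursters among spikers (offensive); near 1"
    "\nclusters them together (defensive). These placements bracket the range"
    "\nexplored by the random placement sweeps."
)
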