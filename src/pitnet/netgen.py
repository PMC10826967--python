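"""Structural networks of pituitary cells and burster-placement strategies.

Pituitary endocrine cells form small, irregular gap-junction networks
adjacent to capillaries.  We emulate them with a random-walk growth
process: start from two connected nodes and repeatedly pick a uniform
random existing node; with probability ``p`` attach a brand-new node to
it, otherwise wire it to another uniform random existing node.  The
result is a connected, undirected simple graph whose degree distribution
is irregular (it can contain hubs), which is what gives burster
placement its leverage.

Each node is labelled an intrinsic *burster* or intrinsic *spiker*.
Placement strategies:

``random``
    uniform choice of the burster set (the null model for the sweeps);
``defensive``
    greedy growth of a connected burster cluster — bursters huddle
    together ("circle the wagons"), maximizing burster homophily;
``offensive``
    greedy dispersal — bursters avoid each other and prefer hubs, to
    touch as many spikers as possible, minimizing burster homophily;
``explicit``
    caller-supplied burster node list.

Homophily statistics: for a burster v, ``gamma_b(v)`` is the fraction of
v's neighbors that are bursters; ``Gamma_b`` is its mean over all
bursters.  ``gamma_s`` / ``Gamma_s`` are the spiker-side analogues
(fraction of a spiker's neighbors that are bursters).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

__all__ = [
    "BURSTER",
    "SPIKER",
    "CellNetwork",
    "GenConfig",
    "HomophilyReport",
    "random_walk_network",
    "assign_types",
    "homophily",
    "write_network_tsv",
    "read_network_tsv",
]

BURSTER = "burster"
SPIKER = "spiker"
_SHORT = {BURSTER: "b", SPIKER: "s"}
_LONG = {"b": BURSTER, "s": SPIKER}

_MAX_EDGE_RETRIES = 100


@dataclass(frozen=True)
class CellNetwork:
    """Undirected labelled cell network.

    Nodes are 0..n_nodes-1; ``edges`` is a frozenset of sorted pairs;
    ``types`` is a per-node tuple of ``"burster"`` / ``"spiker"`` labels,
    or None while the network is still unlabelled.
    """

    n_nodes: int
    edges: frozenset
    types: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("a network needs at least 2 nodes")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) out of range or unsorted")
        if self.types is not None:
            if len(self.types) != self.n_nodes:
                raise ValueError("one type label per node required")
            bad = set(self.types) - {BURSTER, SPIKER}
            if bad:
                raise ValueError(f"unknown cell types: {bad}")
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("network must be connected")

    # -- basic structure ---------------------------------------------------

    @property
    def is_labelled(self) -> bool:
        return self.types is not None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, v: int) -> list:
        return sorted(j if i == v else i for i, j in self.edges if v in (i, j))

    def degree(self, v: int) -> int:
        return sum(1 for e in self.edges if v in e)

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = D - A; the coupling current is g_c * L @ V."""
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        if self.types is not None:
            nx.set_node_attributes(g, dict(enumerate(self.types)), "cell_type")
        return g

    # -- labels ------------------------------------------------------------

    def burster_ids(self) -> list:
        self._require_labels()
        return [v for v, t in enumerate(self.types) if t == BURSTER]

    def spiker_ids(self) -> list:
        self._require_labels()
        return [v for v, t in enumerate(self.types) if t == SPIKER]

    def with_types(self, types: Sequence[str]) -> "CellNetwork":
        return replace(self, types=tuple(types))

    def with_bursters(self, burster_set: Iterable[int]) -> "CellNetwork":
        bs = set(burster_set)
        out_of_range = bs - set(range(self.n_nodes))
        if out_of_range:
            raise ValueError(f"burster ids out of range: {sorted(out_of_range)}")
        return self.with_types(
            [BURSTER if v in bs else SPIKER for v in range(self.n_nodes)]
        )

    def _require_labels(self) -> None:
        if self.types is None:
            raise ValueError("network is unlabelled; assign cell types first")


@dataclass(frozen=True)
class GenConfig:
    """Configuration of the random-walk generator and burster placement.

    ``p`` is the probability that a growth step adds a new node (small p
    means more cross-edges and a denser graph); it is not reported in
    the source study and defaults to 0.7, which yields 10-node networks
    of realistic sparseness.  ``placement`` is one of ``random``,
    ``offensive``, ``defensive``, or an explicit burster-id sequence.
    """

    n: int = 10
    p: float = 0.7
    seed: Optional[int] = None
    burster_fraction: float = 0.5
    placement: Union[str, Sequence[int]] = "random"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]; p = 0 never terminates")
        if not 0 <= self.burster_fraction <= 1:
            raise ValueError("burster_fraction must lie in [0, 1]")
        if isinstance(self.placement, str) and self.placement not in (
            "random",
            "offensive",
            "defensive",
        ):
            raise ValueError(f"unknown placement strategy {self.placement!r}")


@dataclass(frozen=True)
class HomophilyReport:
    """Per-node and population homophily.

    ``gamma_b[v]`` (bursters) and ``gamma_s[v]`` (spikers) map node id to
    the fraction of its neighbors that are bursters.  The population
    means ``Gamma_b`` / ``Gamma_s`` are None when the respective
    population is empty — deliberately flagged, never silently zero.
    """

    gamma_b: dict
    gamma_s: dict
    Gamma_b: Optional[float]
    Gamma_s: Optional[float]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def random_walk_network(cfg: GenConfig, rng: Optional[np.random.Generator] = None) -> CellNetwork:
    """Grow a connected simple graph with ``cfg.n`` nodes by random walk.

    Starts from two connected nodes.  Each iteration picks a uniform
    random existing node u; with probability ``p`` a new node is
    attached to u, otherwise an edge is drawn from u to a uniform random
    other existing node (redrawing the partner a bounded number of times
    if the edge already exists, which biases the edge count slightly low
    in dense graphs).  Returns an unlabelled network.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    edges = {(0, 1)}
    n_cur = 2
    while n_cur < cfg.n:
        u = int(rng.integers(n_cur))
        if rng.random() < cfg.p:
            edges.add(tuple(sorted((u, n_cur))))
            n_cur += 1
        else:
            for _ in range(_MAX_EDGE_RETRIES):
                w = int(rng.integers(n_cur))
                e = tuple(sorted((u, w)))
                if w != u and e not in edges:
                    edges.add(e)
                    break
            # all retries duplicate/self: u is saturated, skip this round
    return CellNetwork(n_nodes=cfg.n, edges=frozenset(edges))


def _n_bursters(n: int, fraction: float) -> int:
    # round-half-up so fraction 0.25 of 10 gives 3, matching intuition
    return int(np.floor(fraction * n + 0.5))


def _gamma_b_of(net: CellNetwork, burster_set: set) -> float:
    if not burster_set:
        return float("nan")
    vals = []
    for v in burster_set:
        nb = net.neighbors(v)
        vals.append(sum(1 for w in nb if w in burster_set) / len(nb))
    return float(np.mean(vals))


def _defensive_placement(net: CellNetwork, k: int, rng: np.random.Generator) -> set:
    """Grow a connected burster cluster; best Gamma_b over all start nodes."""
    best, best_gamma = None, -1.0
    for start in range(net.n_nodes):
        cluster = {start}
        while len(cluster) < k:
            frontier = sorted(
                {w for v in cluster for w in net.neighbors(v)} - cluster
            )
            if not frontier:  # cluster spans a component; cannot happen (connected)
                frontier = sorted(set(range(net.n_nodes)) - cluster)
            scores = [_gamma_b_of(net, cluster | {w}) for w in frontier]
            cluster.add(frontier[int(np.argmax(scores))])
        g = _gamma_b_of(net, cluster)
        if g > best_gamma:
            best, best_gamma = cluster, g
    return best


def _offensive_placement(net: CellNetwork, k: int, rng: np.random.Generator) -> set:
    """Disperse bursters: prefer high-degree nodes not adjacent to bursters."""
    chosen: set = set()
    degrees = {v: net.degree(v) for v in range(net.n_nodes)}
    while len(chosen) < k:
        candidates = sorted(set(range(net.n_nodes)) - chosen)
        non_adjacent = [
            v for v in candidates if not any(w in chosen for w in net.neighbors(v))
        ]
        pool = non_adjacent if non_adjacent else candidates
        scores = [
            (_gamma_b_of(net, chosen | {v}), -degrees[v], v) for v in pool
        ]
        _, _, pick = min(scores)
        chosen.add(pick)
    return chosen


def assign_types(
    net: CellNetwork,
    cfg: GenConfig,
    rng: Optional[np.random.Generator] = None,
) -> CellNetwork:
    """Label nodes as bursters/spikers according to ``cfg.placement``.

    The burster count is round(burster_fraction * n).  ``random`` draws
    the burster set uniformly; ``defensive``/``offensive`` use greedy
    heuristics that respectively maximize and minimize burster homophily;
    an explicit id sequence is used as given.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not isinstance(cfg.placement, str):
        return net.with_bursters(cfg.placement)
    k = _n_bursters(net.n_nodes, cfg.burster_fraction)
    if cfg.placement == "random":
        chosen = set(rng.choice(net.n_nodes, size=k, replace=False).tolist()) if k else set()
    elif cfg.placement == "defensive":
        chosen = _defensive_placement(net, k, rng) if k else set()
    else:  # offensive
        chosen = _offensive_placement(net, k, rng) if k else set()
    return net.with_bursters(chosen)


def generate(cfg: GenConfig) -> CellNetwork:
    """Convenience: grow a network and label it in one seeded call."""
    rng = np.random.default_rng(cfg.seed)
    return assign_types(random_walk_network(cfg, rng), cfg, rng)


# ---------------------------------------------------------------------------
# Homophily
# ---------------------------------------------------------------------------

def homophily(net: CellNetwork) -> HomophilyReport:
    """Burster/spiker homophily statistics of a labelled network."""
    net._require_labels()
    bursters = set(net.burster_ids())
    gamma_b, gamma_s = {}, {}
    for v in range(net.n_nodes):
        nb = net.neighbors(v)
        frac = sum(1 for w in nb if w in bursters) / len(nb)
        (gamma_b if v in bursters else gamma_s)[v] = frac
    return HomophilyReport(
        gamma_b=gamma_b,
        gamma_s=gamma_s,
        Gamma_b=float(np.mean(list(gamma_b.values()))) if gamma_b else None,
        Gamma_s=float(np.mean(list(gamma_s.values()))) if gamma_s else None,
    )


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_network_tsv(net: CellNetwork, path: Union[str, Path]) -> None:
    """Write ``#nodes``/``#types`` headers then one ``i<TAB>j`` line per edge."""
    lines = [f"#nodes {net.n_nodes}"]
    if net.types is not None:
        lines.append("#types " + ",".join(_SHORT[t] for t in net.types))
    lines += [f"{i}\t{j}" for i, j in sorted(net.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_network_tsv(path: Union[str, Path]) -> CellNetwork:
    n_nodes, types, edges = None, None, set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#nodes"):
            n_nodes = int(line.split()[1])
        elif line.startswith("#types"):
            types = tuple(_LONG[t.strip()] for t in line.split(None, 1)[1].split(","))
        else:
            i, j = map(int, line.split("\t"))
            edges.add(tuple(sorted((i, j))))
    if n_nodes is None:
        raise ValueError("missing '#nodes' header")
    return CellNetwork(n_nodes=n_nodes, edges=frozenset(edges), types=types)
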