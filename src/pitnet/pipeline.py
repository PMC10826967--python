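"""Secretion-strategy experiments: placement sweeps, bins, gamma_s spread.

The driving question: given a fixed structural network and a fixed
number of intrinsic bursters, where should the bursters sit to maximize
hormone output?  For each candidate placement the network is simulated,
and the secretion surrogate is averaged over all cells and the post-
transient analysis window, giving one number <s> per placement.
Plotting <s> against the burster homophily Gamma_b over many random
placements reveals the strategy landscape: with many bursters an
*offensive* (dispersed, low Gamma_b) arrangement wins; with few
bursters a *defensive* (clustered, high Gamma_b) arrangement wins.

All placements of a sweep share the structural network and differ only
in the per-cell BK conductance, so they are simulated in lock-step
batches by :func:`pitnet.netsim.simulate_batch`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import events as ev
from .model_core import CellParams, burster_params, spiker_params
from .netgen import CellNetwork, HomophilyReport, homophily
from .netsim import SimConfig, Trajectory, simulate_batch

__all__ = [
    "PlacementResult",
    "BinSummary",
    "average_secretion",
    "sweep_placements",
    "bin_average",
    "gamma_s_histogram",
    "matched_subpopulations",
    "results_to_frame",
    "results_to_csv",
]


@dataclass(frozen=True)
class PlacementResult:
    """Outcome of one burster placement on the structural network."""

    placement_id: int
    burster_ids: tuple
    gamma_b_mean: Optional[float]  # Gamma_b; None if no bursters
    gamma_s_mean: Optional[float]  # Gamma_s; None if no spikers
    s_mean: float                  # <s>: network-and-time-averaged secretion
    converted: tuple               # per-cell conversion flags (bursting?)
    init_seed: int

    @property
    def n_converted_spikers(self) -> int:
        """Intrinsic spikers whose event train is majority-burst."""
        bs = set(self.burster_ids)
        return sum(
            1 for v, flag in enumerate(self.converted) if v not in bs and flag
        )


@dataclass(frozen=True)
class BinSummary:
    """Equal-width Gamma_b bins with per-bin mean <s> (the binned curve).

    ``s_mean`` is NaN for empty bins (flagged by ``count == 0``, never
    zero-filled).
    """

    edges: np.ndarray    # n_bins + 1 edges on [0, 1]
    count: np.ndarray    # placements per bin
    s_mean: np.ndarray   # mean <s> per bin

    @property
    def n_bins(self) -> int:
        return len(self.count)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def average_secretion(traj: Trajectory, window: Optional[tuple] = None) -> float:
    """<s>: secretion averaged over all cells and the analysis window."""
    w = traj.window(*window) if window else traj.window()
    if w.times.size == 0:
        raise ValueError("empty averaging window")
    return float(w.s.mean())


def bin_average(
    results: Sequence[PlacementResult],
    n_bins: int = 10,
) -> BinSummary:
    """Bin placements by Gamma_b into equal-width bins on [0, 1].

    Bins are right-open except the last, which includes Gamma_b = 1.
    """
    if not results:
        raise ValueError("bin_average needs at least one placement result")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    gb = np.array([r.gamma_b_mean for r in results], dtype=float)
    s = np.array([r.s_mean for r in results], dtype=float)
    idx = np.minimum(np.digitize(gb, edges) - 1, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    s_mean = np.full(n_bins, np.nan)
    for k in range(n_bins):
        if count[k]:
            s_mean[k] = s[idx == k].mean()
    return BinSummary(edges=edges, count=count, s_mean=s_mean)


def gamma_s_histogram(
    nets: Sequence[CellNetwork],
    bins: Union[int, np.ndarray] = 10,
) -> dict:
    """Pooled histogram of per-spiker gamma_s over a subpopulation of networks.

    Returns ``counts``, ``edges``, the pooled ``values``, and their
    ``variance``.  Total histogram mass equals the pooled spiker count.
    """
    values: List[float] = []
    for net in nets:
        rep = homophily(net)
        if not rep.gamma_s:
            raise ValueError("a network in the subpopulation has no spikers")
        values.extend(rep.gamma_s.values())
    values_arr = np.array(values)
    counts, edges = np.histogram(values_arr, bins=bins, range=(0.0, 1.0))
    return {
        "counts": counts,
        "edges": edges,
        "values": values_arr,
        "variance": float(values_arr.var()),
    }


# ---------------------------------------------------------------------------
# Placement sweep
# ---------------------------------------------------------------------------

def _sample_placements(
    n_nodes: int, k: int, n_placements: int, rng: np.random.Generator
) -> List[tuple]:
    """Distinct burster sets of size k, uniform without replacement.

    Falls back to full enumeration when the number of requested
    placements approaches the number of possible sets.
    """
    from math import comb

    total = comb(n_nodes, k)
    if n_placements > total:
        raise ValueError(
            f"{n_placements} distinct placements requested but only {total} exist"
        )
    if n_placements > total // 2:
        from itertools import combinations

        all_sets = list(combinations(range(n_nodes), k))
        pick = rng.choice(total, size=n_placements, replace=False)
        return [all_sets[i] for i in pick]
    seen = set()
    out: List[tuple] = []
    while len(out) < n_placements:
        cand = tuple(sorted(rng.choice(n_nodes, size=k, replace=False).tolist()))
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def sweep_placements(
    net: CellNetwork,
    fraction: float,
    n_placements: int,
    simcfg: SimConfig,
    seed: Optional[int] = None,
    burster: Optional[CellParams] = None,
    spiker: Optional[CellParams] = None,
    chunk_size: int = 50,
    detect_conversion: bool = True,
    backend: Optional[str] = None,
) -> List[PlacementResult]:
    """Simulate many random burster placements on one structural network.

    Placements are distinct burster sets of size round(fraction * n),
    sampled uniformly without replacement.  Each placement gets its own
    seeded initial-condition jitter.  Per placement: Gamma_b, Gamma_s,
    <s>, and (optionally) per-cell conversion flags from the classified
    event trains.  Fully deterministic given ``seed``.
    """
    k = int(np.floor(fraction * net.n_nodes + 0.5))
    if k == 0:
        raise ValueError("burster fraction yields zero bursters")
    rng = np.random.default_rng(seed)
    placements = _sample_placements(net.n_nodes, k, n_placements, rng)
    init_seeds = rng.integers(2**31, size=n_placements)
    b_par = burster or burster_params()
    s_par = spiker or spiker_params()
    results: List[PlacementResult] = []
    for lo in range(0, n_placements, chunk_size):
        hi = min(lo + chunk_size, n_placements)
        chunk = placements[lo:hi]
        gbk = np.full((len(chunk), net.n_nodes), s_par.g_bk)
        for r, bset in enumerate(chunk):
            gbk[r, list(bset)] = b_par.g_bk
        out = simulate_batch(
            net, gbk, simcfg,
            base_params=s_par,
            init_seeds=init_seeds[lo:hi],
            record_v=detect_conversion,
            backend=backend,
        )
        dt = simcfg.dt
        for r, bset in enumerate(chunk):
            labelled = net.with_bursters(bset)
            rep = homophily(labelled)
            if detect_conversion:
                flags = []
                for cell in range(net.n_nodes):
                    evs = ev.classify_events(
                        ev.detect_events(out["v"][r, cell], dt)
                    )
                    train = ev.EventTrain(
                        cell=cell, events=tuple(evs),
                        window=(float(out["times"][0]), float(out["times"][-1])),
                    )
                    flags.append(ev.is_converted_burster(train)[0])
                flags = tuple(flags)
            else:
                flags = tuple([None] * net.n_nodes)
            results.append(
                PlacementResult(
                    placement_id=lo + r,
                    burster_ids=tuple(bset),
                    gamma_b_mean=rep.Gamma_b,
                    gamma_s_mean=rep.Gamma_s,
                    s_mean=float(out["s_mean"][r].mean()),
                    converted=flags,
                    init_seed=int(init_seeds[lo + r]),
                )
            )
    return results


# ---------------------------------------------------------------------------
# Low/high-secreting subpopulations (gamma_s spread analysis)
# ---------------------------------------------------------------------------

def matched_subpopulations(
    results: Sequence[PlacementResult],
    net: CellNetwork,
    match_tol: float = 0.1,
    min_size: int = 10,
) -> dict:
    """Split a matched-(Gamma_b, Gamma_s) subpopulation at its median <s>.

    Placements are grouped by (Gamma_b, Gamma_s) rounded to multiples of
    ``match_tol``; the most populous group with at least ``min_size``
    members is kept, sorted by <s>, and split into low- and high-
    secreting halves.  Returns the two halves as labelled networks plus
    their pooled gamma_s variances.
    """
    groups: dict = {}
    for r in results:
        if r.gamma_b_mean is None or r.gamma_s_mean is None:
            continue
        key = (
            round(r.gamma_b_mean / match_tol),
            round(r.gamma_s_mean / match_tol),
        )
        groups.setdefault(key, []).append(r)
    eligible = [g for g in groups.values() if len(g) >= min_size]
    if not eligible:
        raise ValueError(
            f"no matched (Gamma_b, Gamma_s) group of size >= {min_size}"
        )
    group = max(eligible, key=len)
    group = sorted(group, key=lambda r: r.s_mean)
    half = len(group) // 2
    low, high = group[:half], group[half:]
    low_nets = [net.with_bursters(r.burster_ids) for r in low]
    high_nets = [net.with_bursters(r.burster_ids) for r in high]
    low_hist = gamma_s_histogram(low_nets)
    high_hist = gamma_s_histogram(high_nets)
    return {
        "low": low,
        "high": high,
        "low_nets": low_nets,
        "high_nets": high_nets,
        "low_gamma_s_variance": low_hist["variance"],
        "high_gamma_s_variance": high_hist["variance"],
        "low_hist": low_hist,
        "high_hist": high_hist,
        "group_size": len(group),
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence[PlacementResult]) -> pd.DataFrame:
    rows = [
        {
            "placement_id": r.placement_id,
            "seed": r.init_seed,
            "burster_ids": ";".join(map(str, r.burster_ids)),
            "gamma_b_mean": r.gamma_b_mean,
            "gamma_s_mean": r.gamma_s_mean,
            "s_mean": r.s_mean,
            "n_converted": r.n_converted_spikers,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def results_to_csv(results: Sequence[PlacementResult], path: Union[str, Path]) -> None:
    results_to_frame(results).to_csv(path, index=False)


def bins_to_frame(summary: BinSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_lo": summary.edges[:-1],
            "bin_hi": summary.edges[1:],
            "count": summary.count,
            "s_mean": summary.s_mean,
        }
    )
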