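"""How many sentinel nodes are enough to stand for the full network.

A k-node subset is judged by how well its cumulative current-density map
reproduces the full-complement map (Spearman correlation at shared random
pixels) and by how stable its MPER estimate is.  The sweep draws an
independent random k-subset for every k, so successive estimates are not
nested; the sufficiency rule is explicit — the smallest k from which the
correlation stays at or above the threshold.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circuit import NodePixel, PairwiseSolver, ResistorGrid, pairwise_all
from .indicators import compare_current_maps, mper

__all__ = ["node_count_sweep", "detect_sufficiency"]


def node_count_sweep(
    grid: ResistorGrid,
    full_nodes: Sequence[NodePixel],
    k_values: Iterable[int] | None = None,
    n_samples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep subset sizes k, comparing each subset map to the full-N map.

    The full-complement cumulative map is computed once.  For each k an
    independent uniform random k-subset is drawn (seeded), its pairwise
    solve run, and three summaries recorded: Spearman rho of its current
    map against the full map at ``n_samples`` shared random pixels, mean
    current density over valid pixels, and MPER.  Node potential columns
    are cached across subsets, so the sweep costs little more than the
    union of pair solves.

    Returns a DataFrame with one row per k: ``k, rho, mean_current,
    mper, n_pairs, seed``.
    """
    full_nodes = list(full_nodes)
    N = len(full_nodes)
    if N < 3:
        raise ValueError("need at least three nodes to sweep")
    if k_values is None:
        k_values = range(2, N + 1)
    k_values = sorted(set(int(k) for k in k_values))
    if k_values[0] < 2 or k_values[-1] > N:
        raise ValueError(f"k values must lie in [2, {N}]")

    rng = np.random.default_rng(seed)
    solver = PairwiseSolver(grid)
    full = pairwise_all(grid, full_nodes, solver=solver)
    full_map = full.cumulative_current

    rows = []
    for k in k_values:
        idx = rng.choice(N, size=k, replace=False)
        sub = pairwise_all(grid, [full_nodes[i] for i in idx], solver=solver)
        rho = compare_current_maps(sub.cumulative_current, full_map, n_samples=n_samples, seed=rng)
        m, _, n_used = mper(sub)
        rows.append(
            {
                "k": k,
                "rho": rho,
                "mean_current": sub.mean_current(),
                "mper": m,
                "n_pairs": n_used,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def detect_sufficiency(table: pd.DataFrame, rho_threshold: float = 0.99) -> int | None:
    """Smallest k whose rho, and every later k's rho, meets the threshold.

    Persistence matters: a single lucky subset crossing the threshold does
    not count if larger subsets fall back below it.  Returns ``None`` when
    the threshold is never sustained.
    """
    if len(table) == 0:
        raise ValueError("empty sweep table")
    t = table.sort_values("k").reset_index(drop=True)
    ok = (t["rho"] >= rho_threshold).to_numpy()
    # suffix-and: position i true iff ok[i:] all true
    sustained = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.flatnonzero(sustained)
    if hits.size == 0:
        return None
    return int(t["k"].iloc[hits[0]])
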