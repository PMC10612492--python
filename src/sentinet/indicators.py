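"""Network-connectivity indicators built on pairwise effective resistance.

The headline indicator is **MPER**, the mean pairwise effective resistance
over all unordered sentinel-node pairs: a single number summarizing how
well connected a protected-area network is (lower = better connected).
Because the sentinel node set is fixed, MPER recomputed after a land-use
change is directly comparable to the baseline, and the difference
(**dMPER**) has a guaranteed sign: adding a high-cost development can only
raise effective resistances (Rayleigh monotonicity), adding a low-cost park
can only lower them.

Per-node **isolation** is the mean resistance from one node to all others —
an analogue of the Protected Area Isolation index; the grand mean of the
isolation values equals MPER exactly when no pair is unreachable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import PairwiseResult

__all__ = [
    "IndicatorReport",
    "mper",
    "delta_mper",
    "node_isolation",
    "compare_current_maps",
]

logger = logging.getLogger(__name__)


def mper(result: PairwiseResult) -> tuple[float, float, int]:
    """Mean pairwise effective resistance, its SE, and the usable pair count.

    The mean runs over unordered reachable pairs; unreachable pairs
    (different network components) are excluded with a logged count.  The SE
    is the sample standard deviation of the pairwise values divided by
    sqrt(n_pairs) — pairwise values are treated as exchangeable, a
    descriptive convention (pairs sharing a node are not independent).  A
    single usable pair reports SE = 0.
    """
    n = result.n_nodes
    iu = np.triu_indices(n, 1)
    vals = result.resistances[iu]
    reachable = np.isfinite(vals)
    excluded = int((~reachable).sum())
    vals = vals[reachable]
    if vals.size == 0:
        raise ValueError("no reachable node pairs; MPER undefined")
    if excluded:
        logger.warning("MPER excludes %d unreachable pairs of %d", excluded, len(iu[0]))
    m = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return m, se, int(vals.size)


def node_isolation(result: PairwiseResult) -> pd.Series:
    """Mean effective resistance from each sentinel node to all others.

    Higher values mean a more isolated park.  A node with no reachable
    partner gets ``inf``.
    """
    n = result.n_nodes
    if n < 2:
        raise ValueError("node isolation needs at least two nodes")
    R = result.resistances
    iso = np.empty(n)
    for i in range(n):
        row = np.delete(R[i], i)
        finite = row[np.isfinite(row)]
        iso[i] = finite.mean() if finite.size else np.inf
    ids = [nd.park_id for nd in result.nodes]
    return pd.Series(iso, index=pd.Index(ids, name="park_id"), name="isolation_ohms")


@dataclass
class IndicatorReport:
    """MPER ± SE, per-node isolation, and bookkeeping for one network state."""

    mper: float
    se: float
    n_pairs: int
    excluded_pairs: int
    isolation: pd.Series
    node_keys: tuple = ()
    single_pair: bool = False
    label: str = ""
    delta_vs: dict = field(default_factory=dict)

    @classmethod
    def from_pairwise(cls, result: PairwiseResult, label: str = "") -> "IndicatorReport":
        m, se, n_used = mper(result)
        total = result.n_pairs
        return cls(
            mper=m,
            se=se,
            n_pairs=n_used,
            excluded_pairs=total - n_used,
            isolation=node_isolation(result),
            node_keys=tuple((nd.park_id, nd.row, nd.col) for nd in result.nodes),
            single_pair=(n_used == 1),
            label=label,
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mper_ohms": self.mper,
            "se_ohms": self.se,
            "se_definition": "sd of pairwise values / sqrt(n_pairs)",
            "n_pairs": self.n_pairs,
            "excluded_pairs": self.excluded_pairs,
            "single_pair": self.single_pair,
            "isolation_ohms": {k: float(v) for k, v in self.isolation.items()},
            "delta_mper_vs": dict(self.delta_vs),
        }


def delta_mper(current: IndicatorReport, baseline: IndicatorReport) -> float:
    """Change in MPER relative to a baseline computed on the same node set.

    Positive = connectivity loss, negative = gain.  Comparing reports built
    on different sentinel sets is refused: the indicator is only repeatable
    because the node set is fixed.
    """
    if current.node_keys != baseline.node_keys:
        raise ValueError(
            "cannot compare MPER across different sentinel sets: "
            f"{len(current.node_keys)} vs {len(baseline.node_keys)} nodes or differing cells"
        )
    d = current.mper - baseline.mper
    current.delta_vs[baseline.label or "baseline"] = d
    return d


def compare_current_maps(
    a: np.ndarray,
    b: np.ndarray,
    n_samples: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Spearman rank correlation of two current maps at random shared pixels.

    Samples ``n_samples`` distinct valid pixels uniformly (seeded), ranks
    with average-rank ties.  Both maps must share shape and NoData (nan)
    mask; if fewer valid pixels exist than requested, all are used with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mask_a, mask_b = np.isnan(a), np.isnan(b)
    if not np.array_equal(mask_a, mask_b):
        raise ValueError("NoData masks differ between the two maps")
    valid = np.flatnonzero(~mask_a.ravel())
    if valid.size < 2:
        raise ValueError("need at least two valid pixels to correlate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if valid.size < n_samples:
        warnings.warn(
            f"only {valid.size} valid pixels available; using all instead of {n_samples}"
        )
        idx = valid
    else:
        idx = rng.choice(valid, size=n_samples, replace=False)
    rho = stats.spearmanr(a.ravel()[idx], b.ravel()[idx]).statistic
    return float(rho)
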