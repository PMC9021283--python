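"""Closest-distance network proximity between drug targets and a gene module.

The proximity of a drug module T to a disease module S is the average, over
targets t in T, of the shortest-path hop count to the nearest module gene:

    p(T, S) = (1/|T|) * sum_t min_s d(t, s)

with d(t, t) = 0 when a target is itself a module gene. Significance comes
from a degree-preserving randomization: both T and S are replaced by
degree-matched random sets (target-only randomization selectable) and the
observed p is z-scored against the null distribution. Links with
z <= -1.65 are considered closer than expected by chance.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import Interactome
from .nulls import DegreeBins, replicate_rng

Z_CUTOFF_DEFAULT = -1.65


@dataclass
class ProximityResult:
    drug_id: str
    set_id: str
    p: float                  # nan when no target reaches the module
    z: float
    null_mean: float
    null_sd: float
    n_reps: int
    seed: int
    n_targets_used: int
    n_targets_unreachable: int

    @property
    def scored(self) -> bool:
        return not math.isnan(self.p)


def _min_distances(adjacency: dict[str, set[str]], sources: set[str]) -> dict[str, int]:
    """Multi-source BFS: hop distance from each reachable node to the
    nearest source."""
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        node = queue.popleft()
        d = dist[node] + 1
        for nb in adjacency[node]:
            if nb not in dist:
                dist[nb] = d
                queue.append(nb)
    return dist


def _closest(targets: set[str], module: set[str],
             adjacency: dict[str, set[str]]) -> tuple[float, int, int]:
    dist = _min_distances(adjacency, module)
    finite = [dist[t] for t in targets if t in dist]
    n_unreachable = len(targets) - len(finite)
    if not finite:
        return math.nan, 0, n_unreachable
    return sum(finite) / len(finite), len(finite), n_unreachable


def closest_proximity(targets: Iterable[str], module_genes: Iterable[str],
                      interactome: Interactome) -> float:
    """p(T, S): the average shortest-path distance from each drug target to
    its nearest module gene.

    Targets with no path to any module gene are excluded from the average
    (the measure is undefined at infinite distance); if no target reaches
    the module the pair is unscored and ``nan`` is returned. Both sets must
    be non-empty subsets of the interactome.
    """
    t = set(targets)
    s = set(module_genes)
    if not t:
        raise ValueError("empty target set")
    if not s:
        raise ValueError("empty module gene set")
    adj = interactome.adjacency
    for name, members in (("target", t), ("module", s)):
        missing = members - adj.keys()
        if missing:
            raise ValueError(f"{name} genes not in interactome: {sorted(missing)[:5]}")
    p, _, _ = _closest(t, s, adj)
    return p


def proximity_zscore(targets: Iterable[str], module_genes: Iterable[str],
                     interactome: Interactome, n_reps: int = 1000, seed: int = 0,
                     min_bin_size: int = 20, randomize: str = "both",
                     drug_id: str = "", set_id: str = "",
                     bins: DegreeBins | None = None) -> ProximityResult:
    """Observed proximity and its degree-preserving randomization z-score.

    ``randomize="both"`` (default) draws degree-matched stand-ins for the
    target set and the module in every null replicate; ``"targets"``
    randomizes targets only. Null replicates in which no stand-in target
    reaches the stand-in module are dropped from the null. Deterministic
    under (seed, n_reps) via per-replicate RNG substreams.
    """
    if randomize not in ("both", "targets"):
        raise ValueError(f"randomize must be 'both' or 'targets', got {randomize!r}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    t = set(targets)
    s = set(module_genes)
    adj = interactome.adjacency
    p_obs, n_used, n_unreach = _closest(t, s, adj)
    if not t or not s:
        raise ValueError("empty set after interactome restriction")
    if bins is None:
        bins = DegreeBins(interactome, min_bin_size=min_bin_size)
    null = []
    for r in range(n_reps):
        rng = replicate_rng(seed, r)
        t_r = bins.sample_matched(t, rng)
        s_r = bins.sample_matched(s, rng) if randomize == "both" else s
        p_r, _, _ = _closest(t_r, s_r, adj)
        if not math.isnan(p_r):
            null.append(p_r)
    null = np.asarray(null)
    if math.isnan(p_obs) or null.size < 2:
        return ProximityResult(drug_id, set_id, math.nan, math.nan, math.nan,
                               math.nan, n_reps, seed, n_used, n_unreach)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        z = 0.0 if p_obs == mean else math.copysign(math.inf, p_obs - mean)
    else:
        z = (p_obs - mean) / sd
    return ProximityResult(drug_id, set_id, p_obs, z, mean, sd, n_reps, seed,
                           n_used, n_unreach)


def is_significant(z: float, cutoff: float = Z_CUTOFF_DEFAULT) -> bool:
    """True when the proximity z-score passes the z <= -1.65 link rule
    (inclusive); -inf sentinels pass, nan (unscored) never does."""
    if math.isnan(z):
        return False
    return z <= cutoff
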