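"""Enrichment accounting and the permutation test.

Face-wise residue and modification counts, variant-proximal fractions, and a
permutation null for the claim that modified residues concentrate near
surface clusters of sequence variation: the observed number of "hit" sites
(variant-proximal, or variable-face) is compared with draws of the same
number of positions uniformly without replacement from a candidate pool —
by default the surface-exposed residues, since modifying enzymes can only
reach the surface.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Callable, Iterable, Sequence

import numpy as np

from .annotation import MappedSiteSet
from .datamodel import EnrichmentResult, ExposureProfile, FacePartition, ProximitySet

__all__ = ["face_counts", "proximal_fraction", "permutation_enrichment", "EXHAUSTIVE_LIMIT"]

#: Exhaustive enumeration is used when C(|pool|, |observed|) is at most this.
EXHAUSTIVE_LIMIT = 10**5


def face_counts(
    sites: MappedSiteSet,
    faces: FacePartition,
    exposure: ExposureProfile,
    surface_only: bool = True,
) -> dict[str, dict[str, int]]:
    """Residue and modification counts per face.

    Residue count = distinct modified positions on the face (restricted to
    surface-exposed positions when ``surface_only``); modification count =
    total distinct modification types summed over those positions, so a
    residue that can be alternatively modified contributes once per type.
    """
    out = {
        "variable": {"residues": 0, "modifications": 0},
        "conserved": {"residues": 0, "modifications": 0},
    }
    for pos in sites.mapped:
        if surface_only and exposure.is_buried(pos):
            continue
        f = faces.of(pos)
        out[f]["residues"] += 1
        out[f]["modifications"] += len(sites.mods_by_position.get(pos, set()))
    return out


def proximal_fraction(sites: MappedSiteSet, prox: ProximitySet) -> tuple[int, int, float]:
    """How many mapped sites have at least one proximal variant.

    ``prox`` must have been computed with the mapped site positions as
    queries and the variant positions as targets.
    """
    n_total = len(sites.mapped)
    if n_total == 0:
        raise ValueError("no mapped sites: proximal fraction undefined")
    proximal = prox.proximal_queries()
    n_proximal = sum(1 for p in sites.mapped if p in proximal)
    return n_proximal, n_total, n_proximal / n_total


def permutation_enrichment(
    observed_sites: Iterable[int],
    candidate_pool: Iterable[int],
    is_hit: Callable[[int], bool],
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> EnrichmentResult:
    """Permutation test for enrichment of hits among the observed sites.

    The statistic is T = number of observed sites for which ``is_hit`` holds.
    Under the null, |observed| positions are drawn uniformly without
    replacement from the pool; the one-sided p-value carries the +1
    small-sample correction, ``p = (1 + #{T* ≥ T}) / (n_perm + 1)``, so it is
    never exactly zero. When C(|pool|, |observed|) ≤ ``exhaustive_limit`` the
    null is enumerated exactly instead (the p-value is then the exact
    hypergeometric tail, reported with n_perm = number of enumerated draws
    and no +1 correction). Fully deterministic given the seed.
    """
    observed = sorted(set(observed_sites))
    pool = sorted(set(candidate_pool))
    if not set(observed) <= set(pool):
        raise ValueError("observed sites must be a subset of the candidate pool")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    k = len(observed)
    n = len(pool)
    if k == 0:
        raise ValueError("no observed sites")

    hit_flags = np.array([bool(is_hit(p)) for p in pool], dtype=bool)
    pool_index = {p: i for i, p in enumerate(pool)}
    t_obs = int(sum(hit_flags[pool_index[p]] for p in observed))
    pool_hits = int(hit_flags.sum())

    pool_frac = pool_hits / n
    obs_frac = t_obs / k
    fold = obs_frac / pool_frac if pool_frac > 0 else float("inf") if obs_frac > 0 else float("nan")

    n_total_draws = comb(n, k)
    if n_total_draws <= exhaustive_limit:
        # exact enumeration: hypergeometric tail P(T* >= T)
        ge = sum(
            1
            for combo in combinations(range(n), k)
            if int(hit_flags[list(combo)].sum()) >= t_obs
        )
        return EnrichmentResult(
            n_observed=k,
            n_observed_hits=t_obs,
            n_pool=n,
            n_pool_hits=pool_hits,
            fold=fold,
            p_perm=ge / n_total_draws,
            n_perm=n_total_draws,
            seed=seed,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    # vectorized draws without replacement: argpartition of uniform keys
    t_null = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, 65536 // max(n, 1) * 16 or 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
        t_null[done : done + m] = hit_flags[picks].sum(axis=1)
        done += m
    p = (1 + int((t_null >= t_obs).sum())) / (n_perm + 1)
    return EnrichmentResult(
        n_observed=k,
        n_observed_hits=t_obs,
        n_pool=n,
        n_pool_hits=pool_hits,
        fold=fold,
        p_perm=p,
        n_perm=n_perm,
        seed=seed,
        exhaustive=False,
    )
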