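"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's algorithms: edit
cost is found by enumerating common subsequences, pattern containment by
enumerating index combinations, and clustering by recomputing every
inter-cluster distance from scratch at every merge.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from phyloprofiler.synthetic_fixtures import (
    ScenarioConfig,
    generate_scenario,
    write_scenario,
)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def brute_subsequence(needle, haystack) -> bool:
    """Containment by explicit enumeration of index combinations."""
    needle, haystack = tuple(needle), tuple(haystack)
    if len(needle) > len(haystack):
        return False
    return any(
        tuple(haystack[i] for i in idx) == needle
        for idx in itertools.combinations(range(len(haystack)), len(needle))
    )


def brute_edit_cost(a, b) -> int:
    """Minimum insert/delete cost via exhaustive common-subsequence search."""
    a, b = tuple(a), tuple(b)
    best = 0
    for r in range(min(len(a), len(b)), 0, -1):
        for idx in itertools.combinations(range(len(a)), r):
            sub = tuple(a[i] for i in idx)
            if brute_subsequence(sub, b):
                best = r
                break
        if best:
            break
    return len(a) + len(b) - 2 * best


def brute_classify(a, b):
    """Reference decision cascade built on the enumeration primitives."""
    from phyloprofiler.arch_compare import ArchClass

    a, b = tuple(a), tuple(b)
    if not a and not b:
        return ArchClass.NO_DOMAINS
    if a == b:
        return ArchClass.CONSERVED
    if brute_subsequence(a, b):
        return ArchClass.GAIN
    if brute_subsequence(b, a):
        return ArchClass.LOSS
    if Counter(a) == Counter(b):
        return ArchClass.REARRANGEMENT
    return ArchClass.COMPLEX


def brute_agglomerate(dist: np.ndarray, rows: np.ndarray, linkage: str, metric: str):
    """O(n^3) agglomeration recomputing cluster distances from scratch.

    Returns the merge list [(frozenset, frozenset, height), ...] using the
    same tie rule as the implementation (smallest original indices), but a
    completely separate data path: clusters are plain index sets and every
    candidate distance is recomputed from the original pairwise matrix (or
    mean vectors, for centroid linkage) at every step.
    """
    from phyloprofiler.cluster_heatmap import distance_matrix

    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    merges = []
    while len(clusters) > 1:
        scored = []
        for x, y in itertools.combinations(clusters, 2):
            if linkage == "single":
                d = min(dist[i, j] for i in x for j in y)
            elif linkage == "complete":
                d = max(dist[i, j] for i in x for j in y)
            elif linkage == "average":
                d = sum(dist[i, j] for i in x for j in y) / (len(x) * len(y))
            elif linkage == "centroid":
                cx = rows[sorted(x)].mean(axis=0)
                cy = rows[sorted(y)].mean(axis=0)
                d = distance_matrix(np.vstack([cx, cy]), metric)[0, 1]
            scored.append((d, min(min(x), min(y)), max(min(x), min(y)), x, y))
        dmin = min(s[0] for s in scored)
        # Same near-tie convention as the implementation: within a 1e-12
        # band of the minimum, the pair with the smallest original indices
        # wins regardless of ulp-level distance differences.
        candidates = [s for s in scored if s[0] <= dmin + 1e-12]
        d, _, _, x, y = min(candidates, key=lambda s: (s[1], s[2]))
        merges.append((x, y, d))
        clusters = [c for c in clusters if c not in (x, y)] + [x | y]
    return merges


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A seeded 40-gene x 6-species scenario, generated once and written out."""
    config = ScenarioConfig(seed=11, n_genes=40, n_species=6)
    scenario = generate_scenario(config)
    out = tmp_path_factory.mktemp("scenario")
    write_scenario(scenario, out)
    return scenario, out


@pytest.fixture()
def rng():
    import random

    return random.Random(42)
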