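"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — full enumeration, python sets,
explicit loops — and shares no code path with the package.
"""

from __future__ import annotations

import random
from itertools import combinations
from math import sqrt


def exact_wilcoxon_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact rank-sum p by enumerating all group labelings."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # assumes no ties
    n = len(x)
    observed = sum(ranks[v] for v in x)
    mean = n * (len(pooled) + 1) / 2
    obs_dev = abs(observed - mean)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n):
        s = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(s - mean) >= obs_dev - 1e-9:
            count += 1
    return count / total


def bh_stepup(ps: list[float]) -> list[float]:
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(ps[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def overlap_min(a: set, b: set) -> float:
    inter = len([k for k in a if k in b])
    return inter / min(len(a), len(b))


def venn_regions(sample_sets: dict[str, set], groups: dict[str, str]) -> dict:
    regions: dict[tuple, int] = {}
    all_keys = set()
    for s in sample_sets.values():
        all_keys |= s
    for key in all_keys:
        carrying = tuple(
            sorted({groups[sid] for sid, s in sample_sets.items() if key in s})
        )
        regions[carrying] = regions.get(carrying, 0) + 1
    return regions


def public_keys(sample_sets: dict[str, set], min_samples: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in sample_sets.values():
        for key in s:
            counts[key] = counts.get(key, 0) + 1
    return {k: c for k, c in counts.items() if c >= min_samples}


def exclusive_keys(
    sample_sets: dict[str, set], groups: dict[str, str], in_groups: set, min_samples: int
) -> dict[tuple, set]:
    out: dict[tuple, set] = {}
    counts: dict[str, list[str]] = {}
    for sid, s in sample_sets.items():
        for key in s:
            counts.setdefault(key, []).append(sid)
    for key, sids in counts.items():
        gs = {groups[sid] for sid in sids}
        if len(sids) >= min_samples and gs <= in_groups:
            out.setdefault(tuple(sorted(gs)), set()).add(key)
    return out


def brute_downsample(
    counts: list[int], depth: int, iterations: int, seed: int
) -> tuple[list[float], list[float], list[float]]:
    """Per-iteration (simpson, max frequency, unique) under template resampling.

    Uses python's ``random.sample`` on the expanded template list — a
    completely different RNG and algorithm from the implementation.
    """
    rng = random.Random(seed)
    templates = []
    for clone_idx, c in enumerate(counts):
        templates.extend([clone_idx] * c)
    simpson, maxfreq, unique = [], [], []
    for _ in range(iterations):
        draw = rng.sample(templates, depth)
        tally: dict[int, int] = {}
        for t in draw:
            tally[t] = tally.get(t, 0) + 1
        freqs = [c / depth for c in tally.values()]
        simpson.append(sqrt(sum(f * f for f in freqs)))
        maxfreq.append(max(freqs))
        unique.append(float(len(freqs)))
    return simpson, maxfreq, unique
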