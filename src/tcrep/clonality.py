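"""Bulk clonality metrics and the clonal-expansion size profile.

Three metrics summarize a productive repertoire:

* **Simpson clonality** — the square root of Simpson's index,
  ``sqrt(sum p_i^2)`` over productive clone frequencies ``p_i``; ranges
  (0, 1] with 1 meaning a monoclonal sample.
* **Max productive frequency** — the frequency of the single most
  expanded clone.
* **Unique productive rearrangements** — the number of distinct
  productive nucleotide rearrangements; higher means more diverse.

Because template depth varies by orders of magnitude between tissues,
metrics are compared after rarefaction: each sample is repeatedly
downsampled *without replacement* to a common productive-template depth
and the metrics are averaged over iterations.  With depth equal to the
full template count every draw is the whole repertoire, so downsampled
metrics reduce exactly to the plain ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import rng_for
from .models import EmptyRepertoireError, InsufficientDepthError, Repertoire

#: Right-closed expansion-bin edges on clone frequency: a clone at exactly
#: an edge falls in the lower bin (e.g. p = 1e-4 is "small", p = 1e-2 "large").
DEFAULT_BIN_EDGES = (1e-4, 1e-3, 1e-2)
BIN_NAMES = ("small", "medium", "large", "hyperexpanded")


@dataclass(frozen=True)
class ClonalityMetrics:
    """The three bulk metrics plus downsampling provenance.

    ``unique_productive_rearrangements`` is a float because downsampled
    values are averages over iterations.
    """

    simpson_clonality: float
    max_productive_frequency: float
    unique_productive_rearrangements: float
    total_productive_templates: int
    downsampled: bool = False
    depth: int | None = None
    iterations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.downsampled and (self.depth is None or self.iterations is None):
            raise ValueError("downsampled metrics require depth and iterations")


@dataclass(frozen=True)
class ExpansionProfile:
    """Fraction of the repertoire occupied by clones of each expansion size."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"expansion proportions sum to {total}, not 1")


def productive_counts(rep: Repertoire) -> np.ndarray:
    """Template counts of the unique productive nucleotide rearrangements."""
    counts = np.array([c.templates for c in rep.clones if c.is_productive], dtype=np.int64)
    return counts


def clone_frequencies(rep: Repertoire) -> np.ndarray:
    """Productive clone frequencies p_i = templates_i / productive total."""
    counts = productive_counts(rep)
    if counts.size == 0:
        raise EmptyRepertoireError(f"{rep.sample_id}: no productive templates")
    return counts / counts.sum()


def simpson_clonality(freqs: Sequence[float] | np.ndarray) -> float:
    """sqrt(sum p_i^2): 1 for a monoclonal sample, R^(-1/2) for R equal clones."""
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise EmptyRepertoireError("empty frequency vector")
    return float(np.sqrt(np.sum(f * f)))


def max_productive_frequency(freqs: Sequence[float] | np.ndarray) -> float:
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise EmptyRepertoireError("empty frequency vector")
    return float(f.max())


def unique_productive_rearrangements(rep: Repertoire) -> int:
    """Distinct productive nucleotide rearrangements in the sample."""
    return len({c.nucleotide_seq for c in rep.clones if c.is_productive})


def plain_metrics(rep: Repertoire) -> ClonalityMetrics:
    """Undownsampled metrics on the full productive repertoire."""
    freqs = clone_frequencies(rep)
    return ClonalityMetrics(
        simpson_clonality=simpson_clonality(freqs),
        max_productive_frequency=max_productive_frequency(freqs),
        unique_productive_rearrangements=float(unique_productive_rearrangements(rep)),
        total_productive_templates=int(productive_counts(rep).sum()),
    )


def downsampled_metrics(
    rep: Repertoire,
    depth: int = 108,
    iterations: int = 100,
    seed: int = 0,
) -> ClonalityMetrics:
    """Rarefy to ``depth`` productive templates and average over iterations.

    Each iteration draws ``depth`` templates uniformly *without
    replacement* from the productive template multiset (a multivariate
    hypergeometric draw over clones), recomputes the three metrics on the
    draw, and the arithmetic means over iterations are reported.  The
    per-sample random stream is derived from ``(seed, sample_id)`` so a
    sample's draws do not depend on the rest of the cohort.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    counts = productive_counts(rep)
    if counts.size == 0:
        raise EmptyRepertoireError(f"{rep.sample_id}: no productive templates")
    total = int(counts.sum())
    if total < depth:
        raise InsufficientDepthError(
            f"{rep.sample_id}: {total} productive templates < depth {depth}"
        )
    if total == depth:
        # every draw without replacement is the full repertoire: the
        # iteration averages equal the plain metrics exactly
        f = counts / depth
        return ClonalityMetrics(
            simpson_clonality=float(np.sqrt(np.sum(f * f))),
            max_productive_frequency=float(f.max()),
            unique_productive_rearrangements=float(counts.size),
            total_productive_templates=total,
            downsampled=True,
            depth=int(depth),
            iterations=int(iterations),
            seed=int(seed),
        )
    rng = rng_for(seed, "downsample", rep.sample_id)
    simpson = np.empty(iterations)
    maxfreq = np.empty(iterations)
    unique = np.empty(iterations)
    for it in range(iterations):
        draw = rng.multivariate_hypergeometric(counts, depth)
        nz = draw[draw > 0]
        f = nz / depth
        simpson[it] = np.sqrt(np.sum(f * f))
        maxfreq[it] = f.max()
        unique[it] = nz.size
    return ClonalityMetrics(
        simpson_clonality=float(simpson.mean()),
        max_productive_frequency=float(maxfreq.mean()),
        unique_productive_rearrangements=float(unique.mean()),
        total_productive_templates=total,
        downsampled=True,
        depth=int(depth),
        iterations=int(iterations),
        seed=int(seed),
    )


def auto_depth(passed: Sequence[Repertoire]) -> int:
    """Rarefaction depth = minimum productive count among QC-passing samples."""
    if not passed:
        raise EmptyRepertoireError("no QC-passing samples to set a depth from")
    return min(r.productive_templates for r in passed)


def expansion_profile(
    freqs: Sequence[float] | np.ndarray,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> ExpansionProfile:
    """Partition repertoire mass by clone-frequency bin.

    Bins are left-open, right-closed on (0, 1]: small (0, 1e-4], medium
    (1e-4, 1e-3], large (1e-3, 1e-2], hyperexpanded (1e-2, 1].  A bin's
    proportion is the summed frequency of its clones, so the four
    proportions partition the repertoire and sum to 1.
    """
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise EmptyRepertoireError("empty frequency vector")
    if abs(float(f.sum()) - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {f.sum()}, expected 1")
    edges_arr = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges_arr, f, side="left")
    sums = np.bincount(idx, weights=f, minlength=len(edges_arr) + 1)
    props = {name: float(sums[i]) for i, name in enumerate(BIN_NAMES)}
    return ExpansionProfile(proportions=props)
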