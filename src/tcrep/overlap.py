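"""Clone-sharing analyses between repertoires.

All sharing analyses key clones by the CDR3 **amino-acid** sequence of
productive rearrangements (nucleotide variants encoding the same protein
collapse), in contrast to the clonality metrics, which count distinct
nucleotide rearrangements.  Overlap is presence/absence: the paper-style
statistic is the size of the intersection divided by the size of the
smaller repertoire, not an abundance-weighted index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Group, Repertoire, Tissue, UndefinedOverlapError, as_group

logger = logging.getLogger(__name__)


def to_clone_set(rep: Repertoire) -> frozenset[str]:
    """Distinct productive CDR3 amino-acid sequences of a sample."""
    return frozenset(c.amino_acid_seq for c in rep.clones if c.is_productive)


def aa_frequencies(rep: Repertoire) -> dict[str, float]:
    """Productive amino-acid clone frequencies (nucleotide variants pooled)."""
    totals: dict[str, int] = {}
    for c in rep.clones:
        if c.is_productive:
            totals[c.amino_acid_seq] = totals.get(c.amino_acid_seq, 0) + c.templates
    denom = sum(totals.values())
    return {k: v / denom for k, v in totals.items()}


def pairwise_overlap(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / min(|a|, |b|); symmetric; 1.0 when one set contains the other."""
    if not a or not b:
        raise UndefinedOverlapError("overlap with an empty repertoire is undefined")
    return len(a & b) / min(len(a), len(b))


@dataclass
class OverlapMatrix:
    """Symmetric pairwise overlap matrix with unit diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def overlap_matrix(cohort: Sequence[Repertoire]) -> OverlapMatrix:
    ids = [r.sample_id for r in cohort]
    sets = [to_clone_set(r) for r in cohort]
    n = len(cohort)
    values = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        v = pairwise_overlap(sets[i], sets[j])
        values[i, j] = values[j, i] = v
    return OverlapMatrix(sample_ids=ids, values=values)


def group_contrast(
    matrix: OverlapMatrix,
    groups: Mapping[str, Group | str],
    reference: Group | str,
) -> dict[str, list[float]]:
    """Overlap distributions against a reference group.

    For the reference group, returns within-reference overlaps (each
    unordered pair once, self-pairs excluded); for every other group, the
    overlaps of each (reference, other) sample pair.
    """
    ref = as_group(reference)
    out: dict[str, list[float]] = {}
    idx = {sid: i for i, sid in enumerate(matrix.sample_ids)}
    by_group: dict[Group, list[str]] = {}
    for sid in matrix.sample_ids:
        by_group.setdefault(as_group(groups[sid]), []).append(sid)
    ref_ids = by_group.get(ref, [])
    out[ref.value] = [
        float(matrix.values[idx[a], idx[b]]) for a, b in combinations(ref_ids, 2)
    ]
    for g, ids in sorted(by_group.items(), key=lambda kv: kv[0].value):
        if g is ref:
            continue
        out[g.value] = [
            float(matrix.values[idx[a], idx[b]]) for a in ref_ids for b in ids
        ]
    return out


@dataclass(frozen=True)
class VennPartition:
    """Counts of distinct clones by the exact set of groups carrying them.

    Regions are keyed by the sorted tuple of group labels; for three
    groups this is the standard 7-region Venn partition, and the region
    counts sum to the number of distinct clone keys in the tissue.
    """

    region_counts: dict[tuple[str, ...], int]

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())


def _carriers(
    cohort: Sequence[Repertoire],
) -> dict[str, list[str]]:
    """Map each productive amino-acid key to the sorted sample ids carrying it."""
    carriers: dict[str, set[str]] = {}
    for rep in cohort:
        for key in to_clone_set(rep):
            carriers.setdefault(key, set()).add(rep.sample_id)
    return {k: sorted(v) for k, v in carriers.items()}


def venn_partition(
    cohort: Sequence[Repertoire],
    groups: Mapping[str, Group | str],
) -> VennPartition:
    """Assign every distinct clone to the region of groups it occurs in."""
    levels = sorted({as_group(g).value for g in groups.values()})
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(levels) + 1):
        for combo in combinations(levels, r):
            counts[combo] = 0
    for key, samples in _carriers(cohort).items():
        region = tuple(sorted({as_group(groups[s]).value for s in samples}))
        counts[region] += 1
    return VennPartition(region_counts=counts)


@dataclass(frozen=True)
class PublicityRecord:
    """A clone present in ``sample_count`` distinct samples of a tissue."""

    key: str
    sample_count: int
    sample_ids: tuple[str, ...]
    group_counts: dict[str, int] = field(default_factory=dict, hash=False, compare=False)


def publicity(
    cohort: Sequence[Repertoire],
    min_samples: int = 5,
    groups: Mapping[str, Group | str] | None = None,
) -> list[PublicityRecord]:
    """Public clones: present in at least ``min_samples`` distinct samples.

    Sorted by sample count descending, then key lexicographically.
    """
    records = []
    for key, samples in _carriers(cohort).items():
        if len(samples) >= min_samples:
            gcounts: dict[str, int] = {}
            if groups is not None:
                for s in samples:
                    g = as_group(groups[s]).value
                    gcounts[g] = gcounts.get(g, 0) + 1
            records.append(
                PublicityRecord(
                    key=key,
                    sample_count=len(samples),
                    sample_ids=tuple(samples),
                    group_counts=gcounts,
                )
            )
    records.sort(key=lambda r: (-r.sample_count, r.key))
    return records


@dataclass
class ExclusiveSharedResult:
    """Clones shared by >= ``min_samples`` samples, all within ``in_groups``.

    ``partitions`` maps an occupancy pattern (the sorted tuple of
    sub-groups the clone's carriers span) to the clone keys in it;
    ``sample_frequencies`` gives, per carrying sample and partition, the
    fraction of that sample's distinct productive clones belonging to the
    partition.
    """

    in_groups: tuple[str, ...]
    min_samples: int
    partitions: dict[tuple[str, ...], list[str]]
    sample_frequencies: pd.DataFrame


def exclusive_shared(
    cohort: Sequence[Repertoire],
    groups: Mapping[str, Group | str],
    in_groups: Iterable[Group | str],
    min_samples: int = 2,
) -> ExclusiveSharedResult:
    """Shared clones found *only* in samples of ``in_groups``.

    A clone qualifies when it occurs in at least ``min_samples`` samples
    and every carrying sample belongs to ``in_groups``; qualifying clones
    are partitioned by the exact set of sub-groups their carriers span
    (e.g. ART-naive only / ART-experienced only / both).
    """
    wanted = {as_group(g).value for g in in_groups}
    levels = tuple(sorted(wanted))
    partitions: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(levels) + 1):
        for combo in combinations(levels, r):
            partitions[combo] = []
    carriers = _carriers(cohort)
    for key, samples in carriers.items():
        sample_groups = {as_group(groups[s]).value for s in samples}
        if len(samples) >= min_samples and sample_groups <= wanted:
            partitions[tuple(sorted(sample_groups))].append(key)
    for combo in partitions:
        partitions[combo].sort()
    # per-sample fraction of distinct clones falling in each partition
    rows = []
    keysets = {combo: set(keys) for combo, keys in partitions.items()}
    for rep in cohort:
        if as_group(groups[rep.sample_id]).value not in wanted:
            continue
        clone_set = to_clone_set(rep)
        if not clone_set:
            continue
        for combo, keys in keysets.items():
            rows.append(
                {
                    "sample_id": rep.sample_id,
                    "group": as_group(groups[rep.sample_id]).value,
                    "partition": "+".join(combo),
                    "fraction": len(clone_set & keys) / len(clone_set),
                }
            )
    freq = pd.DataFrame(rows, columns=["sample_id", "group", "partition", "fraction"])
    return ExclusiveSharedResult(
        in_groups=levels,
        min_samples=min_samples,
        partitions=partitions,
        sample_frequencies=freq,
    )


def tumor_blood_overlap(
    tumor_set: frozenset[str] | set[str],
    blood_set: frozenset[str] | set[str],
) -> float:
    """Fraction of a patient's tumor clones also found in their blood.

    |tumor ∩ blood| / |tumor| — asymmetric by design: blood clones absent
    from the tumor do not enter the statistic.
    """
    if not tumor_set:
        raise UndefinedOverlapError("tumor clone set is empty")
    return len(tumor_set & blood_set) / len(tumor_set)


def paired_by_patient(
    cohort: Sequence[Repertoire],
    patients: Mapping[str, str],
) -> list[tuple[str, Repertoire, Repertoire]]:
    """Match tumor and blood samples of the same patient.

    ``patients`` maps sample_id -> patient_id.  If a patient has several
    samples of one tissue, the first by sample id is used and a warning
    logged.
    """
    by_patient: dict[str, dict[Tissue, Repertoire]] = {}
    for rep in sorted(cohort, key=lambda r: r.sample_id):
        pid = patients[rep.sample_id]
        slot = by_patient.setdefault(pid, {})
        if rep.tissue in slot:
            logger.warning(
                "patient %s has multiple %s samples; keeping %s",
                pid,
                rep.tissue.value,
                slot[rep.tissue].sample_id,
            )
            continue
        slot[rep.tissue] = rep
    pairs = []
    for pid in sorted(by_patient):
        slot = by_patient[pid]
        if Tissue.TUMOR in slot and Tissue.BLOOD in slot:
            pairs.append((pid, slot[Tissue.TUMOR], slot[Tissue.BLOOD]))
    return pairs
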