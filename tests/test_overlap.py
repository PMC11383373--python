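"""Clone sharing: pairwise overlap, Venn partition, publicity, paired overlap."""

import numpy as np
import pytest

from tcrep.models import CloneRecord, FrameType, Repertoire, Tissue, UndefinedOverlapError
from tcrep.overlap import (
    exclusive_shared,
    group_contrast,
    overlap_matrix,
    pairwise_overlap,
    paired_by_patient,
    publicity,
    to_clone_set,
    tumor_blood_overlap,
    venn_partition,
)

from conftest import make_repertoire
from oracles import exclusive_keys, overlap_min, public_keys, venn_regions

GROUPS3 = ("HIV_neg", "HIV_pos_ART_exp", "HIV_pos_ART_naive")


def rep_from_keys(sample_id, keys, tissue=Tissue.TUMOR):
    clones = [
        CloneRecord(f"NT{sample_id}{i:03d}", k, 1, FrameType.IN_FRAME)
        for i, k in enumerate(sorted(keys))
    ]
    return Repertoire(sample_id=sample_id, tissue=tissue, clones=clones)


def random_cohort(rng, n_samples=8, pool=40, tissue=Tissue.TUMOR):
    """Small random cohort with sample sets drawn from a common key pool."""
    keys = [f"CKEY{i:03d}F" for i in range(pool)]
    reps, groups = [], {}
    for s in range(n_samples):
        size = int(rng.integers(3, 25))
        chosen = rng.choice(pool, size=size, replace=False)
        sid = f"S{s:02d}"
        reps.append(rep_from_keys(sid, [keys[i] for i in chosen], tissue))
        groups[sid] = GROUPS3[int(rng.integers(0, 3))]
    return reps, groups


class TestCloneSet:
    def test_nucleotide_variants_collapse(self):
        rep = Repertoire("x", Tissue.TUMOR, [
            CloneRecord("AAA", "CAF", 2, FrameType.IN_FRAME),
            CloneRecord("AAG", "CAF", 3, FrameType.IN_FRAME),
        ])
        assert to_clone_set(rep) == {"CAF"}

    def test_empty_productive_subset(self):
        rep = Repertoire("x", Tissue.TUMOR, [
            CloneRecord("AAA", "", 2, FrameType.HAS_STOP)
        ])
        assert to_clone_set(rep) == frozenset()

    def test_matches_bruteforce_distinct_count(self, tiny_cohort):
        for rep in tiny_cohort.repertoires[:4]:
            expected = {c.amino_acid_seq for c in rep.clones if c.frame_type.value == "in_frame"}
            assert to_clone_set(rep) == expected


class TestPairwiseOverlap:
    def test_identical_sets(self):
        s = {"a", "b", "c"}
        assert pairwise_overlap(s, s) == 1.0

    def test_disjoint_sets(self):
        assert pairwise_overlap({"a", "b"}, {"c"}) == 0.0

    def test_enumeration_example(self):
        assert pairwise_overlap({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(2 / 3)

    def test_symmetric_and_subset_gives_one(self, rng):
        for _ in range(20):
            a = set(rng.choice(50, size=int(rng.integers(1, 20)), replace=False))
            b = set(rng.choice(50, size=int(rng.integers(1, 20)), replace=False))
            assert pairwise_overlap(a, b) == pairwise_overlap(b, a)
            assert pairwise_overlap(a, a | b) == 1.0

    def test_empty_raises(self):
        with pytest.raises(UndefinedOverlapError):
            pairwise_overlap(set(), {"a"})


class TestOverlapMatrix:
    def test_identical_repertoires_all_ones(self):
        reps = [rep_from_keys(f"S{i}", ["CAF", "CBF"]) for i in range(3)]
        m = overlap_matrix(reps)
        assert np.allclose(m.values, 1.0)

    def test_disjoint_repertoires_identity(self):
        reps = [rep_from_keys(f"S{i}", [f"C{i}{j}F" for j in range(4)]) for i in range(3)]
        m = overlap_matrix(reps)
        assert np.allclose(m.values, np.eye(3))

    def test_matches_set_oracle(self, rng):
        reps, _ = random_cohort(rng)
        m = overlap_matrix(reps)
        sets = {r.sample_id: set(to_clone_set(r)) for r in reps}
        for i, a in enumerate(m.sample_ids):
            for j, b in enumerate(m.sample_ids):
                if i != j:
                    assert m.values[i, j] == pytest.approx(overlap_min(sets[a], sets[b]))

    def test_group_contrast_excludes_self_pairs(self, rng):
        reps, groups = random_cohort(rng, n_samples=9)
        m = overlap_matrix(reps)
        ref = "HIV_pos_ART_naive"
        contrast = group_contrast(m, groups, ref)
        n_ref = sum(1 for g in groups.values() if g == ref)
        assert len(contrast[ref]) == n_ref * (n_ref - 1) // 2


class TestVennPartition:
    def test_clone_in_all_groups_center(self):
        reps = [rep_from_keys(f"S{i}", ["CSHAREDF"]) for i in range(3)]
        groups = {f"S{i}": GROUPS3[i] for i in range(3)}
        v = venn_partition(reps, groups)
        assert v.region_counts[tuple(sorted(GROUPS3))] == 1
        assert v.total == 1

    def test_private_clones_only_exclusive_regions(self):
        reps = [rep_from_keys(f"S{i}", [f"CPRIV{i}F"]) for i in range(3)]
        groups = {f"S{i}": GROUPS3[i] for i in range(3)}
        v = venn_partition(reps, groups)
        for region, count in v.region_counts.items():
            assert count == (1 if len(region) == 1 else 0)

    def test_partition_sums_and_matches_oracle(self, rng):
        reps, groups = random_cohort(rng, n_samples=10)
        v = venn_partition(reps, groups)
        sets = {r.sample_id: set(to_clone_set(r)) for r in reps}
        expected = venn_regions(sets, groups)
        all_keys = set().union(*sets.values())
        assert v.total == len(all_keys)
        for region, count in v.region_counts.items():
            assert count == expected.get(region, 0)

    def test_adding_sample_never_decreases_center(self, rng):
        reps, groups = random_cohort(rng, n_samples=9)
        center = tuple(sorted(set(groups.values())))
        v1 = venn_partition(reps, groups)
        extra = rep_from_keys("S99", sorted(to_clone_set(reps[0]))[:5])
        groups2 = dict(groups, S99=GROUPS3[2])
        v2 = venn_partition(reps + [extra], groups2)
        if center in v1.region_counts and len(set(groups.values())) == 3:
            assert v2.region_counts[center] >= v1.region_counts[center]


class TestPublicity:
    def test_threshold_inclusive(self):
        reps = [rep_from_keys(f"S{i}", ["CPUBF"] + [f"CP{i}F"]) for i in range(5)]
        reps.append(rep_from_keys("S9", ["CXF"]))
        recs = publicity(reps, min_samples=5)
        assert [r.key for r in recs] == ["CPUBF"]
        assert recs[0].sample_count == 5

    def test_below_threshold_excluded(self):
        reps = [rep_from_keys(f"S{i}", ["CPUBF"]) for i in range(4)]
        assert publicity(reps, min_samples=5) == []

    def test_matches_oracle_and_nesting(self, rng):
        reps, groups = random_cohort(rng, n_samples=10)
        sets = {r.sample_id: set(to_clone_set(r)) for r in reps}
        for k in (2, 3, 4):
            recs = publicity(reps, min_samples=k, groups=groups)
            expected = public_keys(sets, k)
            assert {r.key: r.sample_count for r in recs} == expected
        # nesting: records at k+1 are a subset of records at k
        k3 = {r.key for r in publicity(reps, min_samples=3)}
        k2 = {r.key for r in publicity(reps, min_samples=2)}
        assert k3 <= k2

    def test_sorted_by_count_then_key(self, rng):
        reps, _ = random_cohort(rng, n_samples=10)
        recs = publicity(reps, min_samples=2)
        assert recs == sorted(recs, key=lambda r: (-r.sample_count, r.key))


class TestExclusiveShared:
    def test_mixed_group_key_excluded(self):
        reps = [rep_from_keys("S0", ["CKF"]), rep_from_keys("S1", ["CKF"])]
        groups = {"S0": "HIV_neg", "S1": "HIV_pos_ART_exp"}
        res = exclusive_shared(reps, groups, ["HIV_pos_ART_exp", "HIV_pos_ART_naive"], 2)
        assert all(not keys for keys in res.partitions.values())

    def test_naive_only_partition(self):
        reps = [rep_from_keys("S0", ["CKF"]), rep_from_keys("S1", ["CKF"])]
        groups = {"S0": "HIV_pos_ART_naive", "S1": "HIV_pos_ART_naive"}
        res = exclusive_shared(reps, groups, ["HIV_pos_ART_exp", "HIV_pos_ART_naive"], 2)
        assert res.partitions[("HIV_pos_ART_naive",)] == ["CKF"]

    def test_matches_oracle(self, rng):
        reps, groups = random_cohort(rng, n_samples=10)
        wanted = {"HIV_pos_ART_exp", "HIV_pos_ART_naive"}
        res = exclusive_shared(reps, groups, wanted, 2)
        sets = {r.sample_id: set(to_clone_set(r)) for r in reps}
        expected = exclusive_keys(sets, groups, wanted, 2)
        for combo, keys in res.partitions.items():
            assert set(keys) == expected.get(combo, set())


class TestTumorBloodOverlap:
    def test_fraction_example(self):
        tumor = {f"C{i}F" for i in range(10)}
        blood = set(list(tumor)[:4]) | {"CXF", "CYF"}
        assert tumor_blood_overlap(tumor, blood) == pytest.approx(0.4)

    def test_blood_superset_gives_one(self):
        tumor = {"CAF", "CBF"}
        assert tumor_blood_overlap(tumor, tumor | {"CZF"}) == 1.0

    def test_invariant_to_blood_only_clones(self, rng):
        tumor = {f"C{i}F" for i in range(20)}
        blood = set(list(tumor)[:7])
        v1 = tumor_blood_overlap(tumor, blood)
        v2 = tumor_blood_overlap(tumor, blood | {f"CB{i}F" for i in range(100)})
        assert v1 == v2

    def test_empty_tumor_raises(self):
        with pytest.raises(UndefinedOverlapError):
            tumor_blood_overlap(set(), {"CAF"})

    def test_paired_by_patient_matches_tissues(self):
        reps = [
            rep_from_keys("P1_T", ["CAF"], Tissue.TUMOR),
            rep_from_keys("P1_B", ["CAF"], Tissue.BLOOD),
            rep_from_keys("P2_T", ["CBF"], Tissue.TUMOR),
        ]
        patients = {"P1_T": "P1", "P1_B": "P1", "P2_T": "P2"}
        pairs = paired_by_patient(reps, patients)
        assert [p[0] for p in pairs] == ["P1"]
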