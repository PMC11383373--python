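"""Synthetic-cohort generator: determinism, planted parameters, limits."""

import math

import numpy as np
import pytest

from tcrep.clonality import clone_frequencies, plain_metrics, simpson_clonality
from tcrep.models import ConfigError, Group, Tissue
from tcrep.overlap import to_clone_set, tumor_blood_overlap
from tcrep.simulate import (
    CohortConfig,
    generate_clinical,
    generate_cohort,
    generate_epitope_db,
    generate_paired_blood,
    generate_repertoire,
    tiny_config,
)

NAIVE, EXP, NEG = "HIV_pos_ART_naive", "HIV_pos_ART_exp", "HIV_neg"


def small_config(**kw):
    base = dict(
        clone_pool_size={"tumor": 100, "blood": 500},
        public_pool_size=200,
        clonal_concentration={"tumor": {NEG: 3.0, EXP: 3.0, NAIVE: 0.3},
                              "blood": {NEG: 0.05, EXP: 0.05, NAIVE: 0.05}},
        depth_median={"tumor": 300.0, "blood": 2000.0},
        depth_sigma={"tumor": 0.3, "blood": 0.3},
        master_seed=11,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestGenerateRepertoire:
    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        a, _ = generate_repertoire(cfg, NAIVE, "tumor", "S1")
        b, _ = generate_repertoire(cfg, NAIVE, "tumor", "S1")
        assert [
            (c.nucleotide_seq, c.amino_acid_seq, c.templates, c.frame_type)
            for c in a.clones
        ] == [
            (c.nucleotide_seq, c.amino_acid_seq, c.templates, c.frame_type)
            for c in b.clones
        ]

    def test_different_samples_differ(self):
        cfg = small_config()
        a, _ = generate_repertoire(cfg, NAIVE, "tumor", "S1")
        b, _ = generate_repertoire(cfg, NAIVE, "tumor", "S2")
        assert to_clone_set(a) != to_clone_set(b)

    def test_uniform_limit_clonality(self):
        """alpha -> infinity over 100 clones: Simpson clonality -> 0.1."""
        cfg = small_config(
            clonal_concentration={"tumor": {NEG: 1e6, EXP: 1e6, NAIVE: 1e6},
                                  "blood": {NEG: 1e6, EXP: 1e6, NAIVE: 1e6}},
            depth_median={"tumor": 500_000.0, "blood": 2000.0},
            depth_sigma={"tumor": 0.0, "blood": 0.3},
            nt_variant_prob=0.0,
        )
        rep, _ = generate_repertoire(cfg, NEG, "tumor", "S1")
        s = simpson_clonality(clone_frequencies(rep))
        assert abs(s - 0.1) / 0.1 < 0.02

    def test_degenerate_dirichlet_dominant_clone(self):
        """alpha = 1e-3 with total pool mass alpha*C << 1: one clone dominates."""
        cfg = small_config(
            clone_pool_size={"tumor": 20, "blood": 500},
            clonal_concentration={"tumor": {NEG: 1e-3, EXP: 1e-3, NAIVE: 1e-3},
                                  "blood": {NEG: 0.05, EXP: 0.05, NAIVE: 0.05}},
            nt_variant_prob=0.0,
        )
        hits = 0
        for i in range(40):
            rep, _ = generate_repertoire(cfg, NEG, "tumor", f"S{i}")
            if plain_metrics(rep).max_productive_frequency > 0.9:
                hits += 1
        assert hits >= 36  # >= 90% of draws

    def test_productive_fraction_binomial(self):
        """Planted 0.77 productive fraction recovered within 3 binomial SDs."""
        cfg = small_config(
            depth_median={"tumor": 10_000.0, "blood": 2000.0},
            depth_sigma={"tumor": 0.0, "blood": 0.3},
        )
        rep, _ = generate_repertoire(cfg, EXP, "tumor", "S1")
        total = rep.total_templates
        frac = rep.productive_templates / total
        sd = math.sqrt(0.77 * 0.23 / total)
        assert abs(frac - 0.77) < 3 * sd

    def test_repertoire_invariants(self):
        cfg = small_config()
        rep, truth = generate_repertoire(cfg, EXP, "tumor", "S1")
        assert rep.total_templates == sum(c.templates for c in rep.clones)
        assert rep.productive_templates == truth["n_productive"]
        assert all(c.templates >= 1 for c in rep.clones)

    def test_concentration_ordering(self):
        """Lower Dirichlet alpha yields higher measured clonality."""
        means = []
        for alpha in (0.03, 0.3, 3.0):
            cfg = small_config(
                clonal_concentration={"tumor": {NEG: alpha, EXP: alpha, NAIVE: alpha},
                                      "blood": {NEG: 0.05, EXP: 0.05, NAIVE: 0.05}},
            )
            vals = []
            for i in range(25):
                rep, _ = generate_repertoire(cfg, NEG, "tumor", f"S{i}")
                vals.append(plain_metrics(rep).simpson_clonality)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestPairedBlood:
    def test_omega_one_deep_blood(self):
        cfg = small_config(
            paired_overlap={NEG: 1.0, EXP: 1.0, NAIVE: 1.0},
            depth_median={"tumor": 200.0, "blood": 20_000.0},
        )
        tr, _ = generate_repertoire(cfg, EXP, "tumor", "T1")
        br, _ = generate_paired_blood(cfg, tr, EXP, "B1")
        assert tumor_blood_overlap(to_clone_set(tr), to_clone_set(br)) > 0.9

    def test_omega_zero_without_sharing(self):
        cfg = small_config(
            paired_overlap={NEG: 0.0, EXP: 0.0, NAIVE: 0.0},
            sharing_prob={NEG: 0.0, EXP: 0.0, NAIVE: 0.0},
        )
        tr, _ = generate_repertoire(cfg, EXP, "tumor", "T1")
        br, _ = generate_paired_blood(cfg, tr, EXP, "B1")
        assert tumor_blood_overlap(to_clone_set(tr), to_clone_set(br)) == 0.0

    def test_omega_recovery(self):
        """omega = 0.3 recovered by the overlap statistic (mean over pairs)."""
        cfg = small_config(paired_overlap={NEG: 0.3, EXP: 0.3, NAIVE: 0.3})
        vals = []
        for i in range(15):
            tr, _ = generate_repertoire(cfg, EXP, "tumor", f"T{i}")
            br, _ = generate_paired_blood(cfg, tr, EXP, f"B{i}")
            vals.append(tumor_blood_overlap(to_clone_set(tr), to_clone_set(br)))
        assert abs(np.mean(vals) - 0.3) < 0.05

    def test_truth_records_shared_keys(self):
        cfg = small_config(paired_overlap={NEG: 0.3, EXP: 0.3, NAIVE: 0.3})
        tr, _ = generate_repertoire(cfg, EXP, "tumor", "T1")
        br, truth = generate_paired_blood(cfg, tr, EXP, "B1")
        planted = set(truth["incidental_shared"]) | set(truth["injected_shared"])
        realized = to_clone_set(tr) & to_clone_set(br)
        assert planted <= realized

    def test_invalid_omega_rejected(self):
        with pytest.raises(ConfigError):
            small_config(paired_overlap={NEG: 1.5, EXP: 0.1, NAIVE: 0.1})


class TestClinical:
    def test_reproducible(self):
        cfg = small_config()
        pats = [(f"P{i}", EXP) for i in range(10)]
        a = generate_clinical(cfg, pats)
        b = generate_clinical(cfg, pats)
        assert a == b

    def test_art_duration_consistent_with_group(self):
        cfg = small_config()
        pats = [(f"P{i}", g) for i, g in enumerate([NAIVE] * 20 + [EXP] * 20 + [NEG] * 10)]
        for r in generate_clinical(cfg, pats):
            art = r.covariates["art_duration_months"]
            if r.group is Group.HIV_POS_ART_NAIVE:
                assert art is not None and art <= 6.0
            elif r.group is Group.HIV_POS_ART_EXP:
                assert art is not None and art > 6.0
            else:
                assert art is None
            assert r.pfs_months <= r.os_months + 1e-9

    def test_null_effects_similar_survival(self):
        """Zero planted log-HRs: group KM medians statistically close."""
        from tcrep.stats import wilcoxon_rank_sum

        cfg = small_config(log_hr={})
        pats = [(f"P{i}", NAIVE if i % 2 else EXP) for i in range(300)]
        recs = generate_clinical(cfg, pats)
        t_naive = [r.os_months for r in recs if r.group is Group.HIV_POS_ART_NAIVE]
        t_exp = [r.os_months for r in recs if r.group is Group.HIV_POS_ART_EXP]
        assert wilcoxon_rank_sum(t_naive, t_exp).p_value > 0.01

    def test_planted_hr_recovered_by_cox(self):
        from tcrep.stats import cox_fit

        cfg = small_config(log_hr={"group_art_naive": math.log(0.3)},
                           censoring_median=120.0)
        pats = [(f"P{i}", NAIVE if i % 2 else EXP) for i in range(400)]
        recs = generate_clinical(cfg, pats)
        res = cox_fit(recs, "OS", "group_art_naive")
        se = (math.log(res.ci_high) - math.log(res.ci_low)) / (2 * 1.96)
        assert abs(math.log(res.hr) - math.log(0.3)) < 3 * se


class TestEpitopeDB:
    def test_zero_fraction_empty(self):
        cfg = small_config(annotated_fraction=0.0)
        db, truth = generate_epitope_db(cfg, [f"CK{i}F" for i in range(100)])
        assert len(db) == 0 and truth["annotated_keys"] == []

    def test_full_fraction_matches_everything(self):
        from tcrep.annotation import annotate

        cfg = small_config(annotated_fraction=1.0)
        keys = [f"CK{i}F" for i in range(50)]
        db, _ = generate_epitope_db(cfg, keys)
        res = annotate(set(keys), db)
        assert res.matched_fraction == pytest.approx(1.0)

    def test_planted_fraction_binomial(self):
        cfg = small_config(annotated_fraction=0.05)
        keys = [f"CK{i}F" for i in range(4000)]
        db, truth = generate_epitope_db(cfg, keys)
        frac = len(truth["annotated_keys"]) / len(keys)
        sd = math.sqrt(0.05 * 0.95 / len(keys))
        assert abs(frac - 0.05) < 3 * sd


class TestGenerateCohort:
    def test_default_counts(self):
        cfg = CohortConfig(master_seed=5)
        layout_tumor = sum(cfg.tumor_counts.values())
        layout_blood = sum(cfg.blood_counts.values())
        assert layout_tumor == 57 and layout_blood == 21

    def test_tiny_cohort_structure(self, tiny_cohort):
        manifest = tiny_cohort.manifest
        assert (manifest["tissue"] == "tumor").sum() == 6
        assert (manifest["tissue"] == "blood").sum() == 6
        assert manifest["paired"].sum() == 8  # 4 pairs x 2 samples
        assert len(tiny_cohort.clinical) == len(manifest["patient_id"].unique())

    def test_regeneration_identical(self, tiny_cohort, tmp_path):
        from tcrep.simulate import generate_cohort, tiny_config, write_cohort

        again = generate_cohort(tiny_config(master_seed=7))
        write_cohort(tiny_cohort, tmp_path / "a")
        write_cohort(again, tmp_path / "b")
        for p in sorted((tmp_path / "a").rglob("*")):
            if p.is_file():
                q = tmp_path / "b" / p.relative_to(tmp_path / "a")
                assert p.read_bytes() == q.read_bytes(), p.name
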