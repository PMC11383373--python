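"""Synthetic TCR-beta cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes so
every pipeline stage can be checked against planted parameters:

* **Clone sizes** — each sample draws clone frequencies from a symmetric
  Dirichlet over a per-sample clone pool; the concentration ``alpha``
  controls clonality (lower alpha = a few dominant clones), with
  group- and tissue-specific defaults so ART-naive tumors are the most
  clonal stratum.
* **Depth** — productive template totals are log-normal per tissue
  (tumor median 300, blood median 20,700), and each template is
  productive with a tissue-specific probability (0.77 tumor, 0.80
  blood); the remainder becomes out-of-frame / stop-codon clones.
* **Sharing** — a cohort-wide public pool of CDR3 amino-acid sequences;
  each pool clone draws its CDR3 from the public pool (with a Zipf-
  weighted head so some clones recur in many samples) with a per-group
  sharing probability, else receives a fresh private sequence.
* **Paired tumor-blood overlap** — a per-group target fraction omega of
  a patient's observed tumor clones is made to appear in their blood
  repertoire.
* **Survival** — exponential event times under a proportional-hazards
  model with planted log-hazard-ratios, independent exponential
  censoring and an administrative follow-up cap.

Every sample is generated from a stream keyed by (master seed,
sample id), so the whole cohort is a pure function of its configuration
and regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import rng_for
from .annotation import EpitopeDB, write_epitope_db
from .io import DIALECT_WRITERS, write_clinical
from .models import (
    ClinicalRecord,
    CloneRecord,
    ConfigError,
    FrameType,
    Group,
    Repertoire,
    Tissue,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

_G = Group
_NEG, _NAIVE, _EXP = _G.HIV_NEG.value, _G.HIV_POS_ART_NAIVE.value, _G.HIV_POS_ART_EXP.value


def _default_tumor_counts() -> dict[str, int]:
    return {_NEG: 19, _EXP: 27, _NAIVE: 11}


def _default_blood_counts() -> dict[str, int]:
    return {_NEG: 7, _EXP: 7, _NAIVE: 7}


def _default_paired_counts() -> dict[str, int]:
    return {_NEG: 5, _EXP: 5, _NAIVE: 6}


def _default_pool_size() -> dict[str, int]:
    return {"tumor": 200, "blood": 10_000}


def _default_concentration() -> dict[str, dict[str, float]]:
    return {
        "tumor": {_NEG: 3.0, _EXP: 3.0, _NAIVE: 0.3},
        "blood": {_NEG: 0.005, _EXP: 0.005, _NAIVE: 0.005},
    }


def _default_sharing() -> dict[str, float]:
    return {_NEG: 0.15, _EXP: 0.15, _NAIVE: 0.05}


def _default_depth_median() -> dict[str, float]:
    return {"tumor": 300.0, "blood": 20_700.0}


def _default_depth_sigma() -> dict[str, float]:
    return {"tumor": 1.5, "blood": 0.6}


def _default_productive_fraction() -> dict[str, float]:
    return {"tumor": 0.77, "blood": 0.80}


def _default_paired_overlap() -> dict[str, float]:
    return {_NEG: 0.03, _EXP: 0.10, _NAIVE: 0.28}


def _default_species_mix() -> dict[str, float]:
    return {"InfluenzaA": 0.30, "CMV": 0.25, "EBV": 0.20, "HIV": 0.15, "other": 0.10}


def _default_log_hr() -> dict[str, float]:
    # hazard ratios vs the ART-experienced baseline
    return {"group_art_naive": math.log(0.43), "group_hiv_neg": math.log(0.80)}


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the cohort structure of the emulated study: 57 tumors
    (19 HIV-negative / 27 ART-experienced / 11 ART-naive), 21 bloods
    (7/7/7), 16 tumor-blood pairs, tumor and blood productive-template
    medians of 300 and 20,700 and productive fractions of 0.77 and 0.80.
    """

    tumor_counts: dict[str, int] = field(default_factory=_default_tumor_counts)
    blood_counts: dict[str, int] = field(default_factory=_default_blood_counts)
    paired_counts: dict[str, int] = field(default_factory=_default_paired_counts)
    clone_pool_size: dict[str, int] = field(default_factory=_default_pool_size)
    public_pool_size: int = 2000
    public_zipf_exponent: float = 1.0
    sharing_prob: dict[str, float] = field(default_factory=_default_sharing)
    clonal_concentration: dict[str, dict[str, float]] = field(
        default_factory=_default_concentration
    )
    depth_median: dict[str, float] = field(default_factory=_default_depth_median)
    depth_sigma: dict[str, float] = field(default_factory=_default_depth_sigma)
    productive_fraction: dict[str, float] = field(
        default_factory=_default_productive_fraction
    )
    paired_overlap: dict[str, float] = field(default_factory=_default_paired_overlap)
    nt_variant_prob: float = 0.3
    annotated_fraction: float = 0.05
    species_mix: dict[str, float] = field(default_factory=_default_species_mix)
    multi_species_prob: float = 0.05
    baseline_median_os: float = 12.0
    log_hr: dict[str, float] = field(default_factory=_default_log_hr)
    age_log_hr_per_decade: float = 0.0
    censoring_median: float = 48.0
    followup_cap_months: float = 60.0
    progression_hazard_ratio: float = 0.6
    master_seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.sharing_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"sharing_prob[{g}]={p} outside [0,1]")
        for g, w in self.paired_overlap.items():
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"paired_overlap[{g}]={w} outside [0,1]")
        for tissue, by_group in self.clonal_concentration.items():
            for g, a in by_group.items():
                if a <= 0:
                    raise ConfigError(f"clonal_concentration[{tissue}][{g}]={a} must be > 0")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ConfigError("annotated_fraction outside [0,1]")
        for tissue, frac in self.productive_fraction.items():
            if not 0.0 < frac <= 1.0:
                raise ConfigError(f"productive_fraction[{tissue}]={frac} outside (0,1]")
        for counts in (self.tumor_counts, self.blood_counts, self.paired_counts):
            for g, n in counts.items():
                if n < 0:
                    raise ConfigError(f"negative sample count {n} for {g}")
        for g in self.paired_counts:
            if self.paired_counts[g] > min(
                self.tumor_counts.get(g, 0), self.blood_counts.get(g, 0)
            ):
                raise ConfigError(
                    f"paired_counts[{g}] exceeds available tumor or blood samples"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def tiny_config(master_seed: int = 0) -> CohortConfig:
    """A 2-per-group cohort for fast smoke tests."""
    return CohortConfig(
        tumor_counts={_NEG: 2, _EXP: 2, _NAIVE: 2},
        blood_counts={_NEG: 2, _EXP: 2, _NAIVE: 2},
        paired_counts={_NEG: 1, _EXP: 1, _NAIVE: 2},
        clone_pool_size={"tumor": 100, "blood": 1000},
        public_pool_size=300,
        depth_median={"tumor": 300.0, "blood": 3000.0},
        depth_sigma={"tumor": 0.8, "blood": 0.4},
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# Sequence generation


def random_strings(rng: np.random.Generator, n: int, lengths: np.ndarray, alphabet: str) -> np.ndarray:
    """Vectorized random fixed-alphabet strings with per-string lengths."""
    letters = np.array(list(alphabet), dtype="U1")
    out = np.empty(n, dtype=object)
    for L in np.unique(lengths):
        idx = np.nonzero(lengths == L)[0]
        arr = letters[rng.integers(0, len(letters), size=(idx.size, int(L)))]
        out[idx] = np.ascontiguousarray(arr).view(f"U{int(L)}").ravel()
    return out


def random_cdr3s(rng: np.random.Generator, n: int) -> np.ndarray:
    """Synthetic CDR3 amino-acid sequences: 'C' + 8-12 residues + 'F'.

    Biologically naive, but no operation inspects sequence content beyond
    string equality.
    """
    if n == 0:
        return np.empty(0, dtype=object)
    lengths = rng.integers(8, 13, size=n)
    cores = random_strings(rng, n, lengths, AA_ALPHABET)
    return np.array(["C" + c + "F" for c in cores], dtype=object)


def public_pool(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """The cohort-wide public CDR3 pool and its Zipf sampling weights."""
    rng = rng_for(config.master_seed, "public_pool")
    keys = random_cdr3s(rng, config.public_pool_size)
    ranks = np.arange(1, config.public_pool_size + 1, dtype=float)
    weights = ranks ** (-config.public_zipf_exponent)
    weights /= weights.sum()
    return keys, weights


# ---------------------------------------------------------------------------
# Repertoire generation


def generate_repertoire(
    config: CohortConfig,
    group: Group | str,
    tissue: Tissue | str,
    sample_id: str,
) -> tuple[Repertoire, dict]:
    """One synthetic repertoire plus its ground-truth slice.

    The truth dict records the drawn pool frequencies, each pool clone's
    amino-acid key and public/private status, and the realized template
    allocation, so downstream statistics can be recomputed by brute force.
    """
    group = Group(group)
    tissue = Tissue(tissue)
    rng = rng_for(config.master_seed, "repertoire", sample_id)
    C = int(config.clone_pool_size[tissue.value])
    alpha = float(config.clonal_concentration[tissue.value][group.value])
    frac = float(config.productive_fraction[tissue.value])

    freqs = rng.dirichlet(np.full(C, alpha))
    while not np.isfinite(freqs).all() or freqs.sum() <= 0:  # pragma: no cover
        freqs = rng.dirichlet(np.full(C, alpha))

    median = float(config.depth_median[tissue.value])
    sigma = float(config.depth_sigma[tissue.value])
    n_prod = 0
    while n_prod == 0:
        target_prod = rng.lognormal(mean=math.log(median), sigma=sigma)
        total = max(1, int(round(target_prod / frac)))
        n_prod = int(rng.binomial(total, frac))
    n_nonprod = total - n_prod

    # amino-acid keys for the pool: public with per-group probability
    pool_keys_arr, zipf_w = public_pool(config)
    is_public = rng.random(C) < float(config.sharing_prob[group.value])
    keys = np.empty(C, dtype=object)
    n_pub = int(is_public.sum())
    if n_pub:
        keys[is_public] = pool_keys_arr[
            rng.choice(config.public_pool_size, size=n_pub, p=zipf_w)
        ]
    keys[~is_public] = random_cdr3s(rng, C - n_pub)

    counts = rng.multinomial(n_prod, freqs)
    observed = np.nonzero(counts)[0]
    clones: list[CloneRecord] = []
    for i in observed:
        aa = keys[i]
        c = int(counts[i])
        two_variants = c >= 2 and rng.random() < config.nt_variant_prob
        nt_len = 3 * len(aa)
        if two_variants:
            split = int(rng.integers(1, c))
            parts = [split, c - split]
        else:
            parts = [c]
        nts = random_strings(rng, len(parts), np.full(len(parts), nt_len), NT_ALPHABET)
        for nt, part in zip(nts, parts):
            clones.append(
                CloneRecord(
                    nucleotide_seq=str(nt),
                    amino_acid_seq=str(aa),
                    templates=part,
                    frame_type=FrameType.IN_FRAME,
                )
            )
    if n_nonprod > 0:
        k_np = max(1, n_nonprod // 2)
        np_counts = rng.multinomial(n_nonprod, np.full(k_np, 1.0 / k_np))
        np_counts = np_counts[np_counts > 0]
        lengths = 3 * (rng.integers(8, 13, size=np_counts.size) + 2)
        nts = random_strings(rng, np_counts.size, lengths, NT_ALPHABET)
        frames = rng.random(np_counts.size) < 0.5
        for nt, c, stop in zip(nts, np_counts, frames):
            clones.append(
                CloneRecord(
                    nucleotide_seq=str(nt),
                    amino_acid_seq="",
                    templates=int(c),
                    frame_type=FrameType.HAS_STOP if stop else FrameType.OUT_OF_FRAME,
                )
            )
    rep = Repertoire(sample_id=sample_id, tissue=tissue, clones=clones)
    truth = {
        "freqs": freqs,
        "keys": keys,
        "is_public": is_public,
        "counts": counts,
        "n_productive": n_prod,
        "n_nonproductive": n_nonprod,
        "alpha": alpha,
        "group": group.value,
        "tissue": tissue.value,
    }
    return rep, truth


def generate_paired_blood(
    config: CohortConfig,
    tumor_rep: Repertoire,
    group: Group | str,
    sample_id: str,
) -> tuple[Repertoire, dict]:
    """A blood repertoire paired to a tumor sample with planted overlap.

    The target is ``omega = paired_overlap[group]``: after generating an
    independent blood repertoire, enough observed tumor clones are
    grafted onto blood clones (relabeling their amino-acid key, template
    counts untouched) that the realized tumor-in-blood fraction matches
    ``round(omega * n_tumor_clones)``.  Incidental sharing through the
    public pool counts toward the target; if it already exceeds the
    target the repertoire is left as drawn and the truth notes it.
    """
    group = Group(group)
    omega = float(config.paired_overlap[group.value])
    blood_rep, blood_truth = generate_repertoire(config, group, Tissue.BLOOD, sample_id)
    rng = rng_for(config.master_seed, "paired", sample_id)

    tumor_keys = sorted({c.amino_acid_seq for c in tumor_rep.clones if c.is_productive})
    blood_keys = {c.amino_acid_seq for c in blood_rep.clones if c.is_productive}
    n_tumor = len(tumor_keys)
    n_target = int(round(omega * n_tumor))
    incidental = sorted(k for k in tumor_keys if k in blood_keys)
    need = n_target - len(incidental)
    injected: list[str] = []
    if need > 0:
        candidates = [k for k in tumor_keys if k not in blood_keys]
        relabelable = sorted(blood_keys - set(tumor_keys))
        take = min(need, len(candidates), len(relabelable))
        chosen = list(rng.choice(np.array(candidates, dtype=object), size=take, replace=False))
        targets = list(rng.choice(np.array(relabelable, dtype=object), size=take, replace=False))
        relabel = dict(zip(targets, chosen))
        new_clones = []
        for c in blood_rep.clones:
            if c.is_productive and c.amino_acid_seq in relabel:
                new_clones.append(
                    CloneRecord(
                        nucleotide_seq=c.nucleotide_seq,
                        amino_acid_seq=str(relabel[c.amino_acid_seq]),
                        templates=c.templates,
                        frame_type=c.frame_type,
                    )
                )
            else:
                new_clones.append(c)
        blood_rep = Repertoire(
            sample_id=blood_rep.sample_id, tissue=Tissue.BLOOD, clones=new_clones
        )
        injected = [str(k) for k in chosen]
    blood_truth = dict(blood_truth)
    blood_truth.update(
        {
            "omega": omega,
            "paired_tumor": tumor_rep.sample_id,
            "overlap_target": n_target,
            "incidental_shared": incidental,
            "injected_shared": injected,
            "overlap_exceeded": len(incidental) > n_target,
        }
    )
    return blood_rep, blood_truth


# ---------------------------------------------------------------------------
# Clinical records


def _covariates_for(
    rng: np.random.Generator, group: Group
) -> dict[str, float | str | None]:
    cov: dict[str, float | str | None] = {}
    cov["ldh"] = float(round(rng.lognormal(math.log(400), 0.5), 1))
    cov["ecog"] = float(rng.integers(0, 4))
    cov["stage_gt2"] = float(rng.random() < 0.5)
    cov["ki67"] = float(round(rng.uniform(40, 95), 1))
    cov["eber"] = float(rng.random() < 0.10)
    cov["cell_of_origin"] = "GC" if rng.random() < 0.48 else "non-GC"
    if group is Group.HIV_NEG:
        cov["hiv_viral_load"] = None
        cov["cd4_count"] = None
        cov["art_duration_months"] = None
    elif group is Group.HIV_POS_ART_NAIVE:
        cov["hiv_viral_load"] = float(round(rng.lognormal(math.log(9800), 1.0)))
        cov["cd4_count"] = float(round(rng.lognormal(math.log(150), 0.6)))
        cov["art_duration_months"] = float(
            round(min(6.0, rng.lognormal(math.log(0.2), 1.0)), 1)
        )
    else:
        cov["hiv_viral_load"] = 0.0 if rng.random() < 0.7 else float(
            round(rng.lognormal(math.log(200), 1.0))
        )
        cov["cd4_count"] = float(round(rng.lognormal(math.log(350), 0.5)))
        cov["art_duration_months"] = float(
            round(max(6.1, rng.lognormal(math.log(58), 0.6)), 1)
        )
    return cov


def generate_clinical(
    config: CohortConfig,
    patients: Sequence[tuple[str, Group | str]],
) -> list[ClinicalRecord]:
    """Clinical records with proportional-hazards survival.

    Event times are exponential with rate ``log(2)/baseline_median_os``
    scaled by ``exp(eta)``, where ``eta`` sums the planted log-HRs of the
    patient's group indicators (and optionally age).  Progression occurs
    at an extra independent hazard, so PFS <= OS by construction; both
    endpoints share an independent exponential censoring time and a
    follow-up cap.
    """
    lam0 = math.log(2) / config.baseline_median_os
    lam_c = math.log(2) / config.censoring_median
    records = []
    for pid, group in patients:
        group = Group(group)
        rng = rng_for(config.master_seed, "clinical", pid)
        age = float(np.clip(round(rng.normal(46, 13)), 18, 85))
        sex = "M" if rng.random() < 0.55 else "F"
        eta = 0.0
        if group is Group.HIV_POS_ART_NAIVE:
            eta += config.log_hr.get("group_art_naive", 0.0)
        elif group is Group.HIV_NEG:
            eta += config.log_hr.get("group_hiv_neg", 0.0)
        eta += config.age_log_hr_per_decade * (age - 46.0) / 10.0
        lam = lam0 * math.exp(eta)
        t_death = rng.exponential(1.0 / lam)
        t_prog = rng.exponential(1.0 / (lam * config.progression_hazard_ratio))
        t_cens = min(rng.exponential(1.0 / lam_c), config.followup_cap_months)
        os_months = round(min(t_death, t_cens), 1)
        os_event = t_death <= t_cens
        t_pfs = min(t_prog, t_death)
        pfs_months = round(min(t_pfs, t_cens), 1)
        pfs_event = t_pfs <= t_cens
        pfs_months = min(pfs_months, os_months)
        records.append(
            ClinicalRecord(
                patient_id=pid,
                group=group,
                age=age,
                sex=sex,
                os_months=max(os_months, 0.1),
                os_event=bool(os_event),
                pfs_months=max(min(pfs_months, max(os_months, 0.1)), 0.1),
                pfs_event=bool(pfs_event),
                covariates=_covariates_for(rng, group),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Epitope database


def generate_epitope_db(
    config: CohortConfig, keys: Sequence[str]
) -> tuple[EpitopeDB, dict]:
    """Plant species annotations on a fraction of the given CDR3 keys."""
    rng = rng_for(config.master_seed, "epitope_db")
    keys = sorted(set(keys))
    species_names = sorted(config.species_mix)
    probs = np.array([config.species_mix[s] for s in species_names], dtype=float)
    probs /= probs.sum()
    rows = []
    annotated = []
    for key in keys:
        if rng.random() < config.annotated_fraction:
            annotated.append(key)
            n_species = 2 if rng.random() < config.multi_species_prob else 1
            chosen = rng.choice(len(species_names), size=n_species, replace=False, p=probs)
            for si in chosen:
                epitope = "".join(
                    AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), size=9)
                )
                rows.append(
                    {
                        "cdr3_aa": key,
                        "species": species_names[int(si)],
                        "epitope": epitope,
                        "mhc_class": "MHCI" if rng.random() < 0.7 else "MHCII",
                    }
                )
    df = pd.DataFrame(rows, columns=["cdr3_aa", "species", "epitope", "mhc_class"])
    truth = {"annotated_keys": annotated, "annotated_fraction": config.annotated_fraction}
    return EpitopeDB(entries=df), truth


# ---------------------------------------------------------------------------
# Cohort orchestration


@dataclass
class SyntheticCohort:
    config: CohortConfig
    repertoires: list[Repertoire]
    clinical: list[ClinicalRecord]
    epitope_db: EpitopeDB
    manifest: pd.DataFrame  # sample_id, patient_id, group, tissue, paired
    truth: dict


def _patient_layout(config: CohortConfig) -> list[dict]:
    """Deterministic patient/sample layout from the per-group counts."""
    layout = []
    idx = 1
    for gname in (_NEG, _EXP, _NAIVE):
        n_tumor = config.tumor_counts.get(gname, 0)
        n_blood = config.blood_counts.get(gname, 0)
        n_paired = config.paired_counts.get(gname, 0)
        n_tumor_only = n_tumor - n_paired
        n_blood_only = n_blood - n_paired
        for kind, count in (
            ("paired", n_paired),
            ("tumor_only", n_tumor_only),
            ("blood_only", n_blood_only),
        ):
            for _ in range(count):
                layout.append({"patient_id": f"P{idx:03d}", "group": gname, "kind": kind})
                idx += 1
    return layout


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort in memory: repertoires, clinical, epitopes."""
    layout = _patient_layout(config)
    repertoires: list[Repertoire] = []
    manifest_rows = []
    truth: dict = {"samples": {}, "config_hash": config.config_hash()}
    for pat in layout:
        pid, gname, kind = pat["patient_id"], pat["group"], pat["kind"]
        tumor_rep = None
        if kind in ("paired", "tumor_only"):
            sid = f"{pid}_T"
            tumor_rep, t_truth = generate_repertoire(config, gname, Tissue.TUMOR, sid)
            repertoires.append(tumor_rep)
            truth["samples"][sid] = t_truth
            manifest_rows.append(
                {"sample_id": sid, "patient_id": pid, "group": gname, "tissue": "tumor",
                 "paired": kind == "paired"}
            )
        if kind in ("paired", "blood_only"):
            sid = f"{pid}_B"
            if kind == "paired":
                blood_rep, b_truth = generate_paired_blood(config, tumor_rep, gname, sid)
            else:
                blood_rep, b_truth = generate_repertoire(config, gname, Tissue.BLOOD, sid)
            repertoires.append(blood_rep)
            truth["samples"][sid] = b_truth
            manifest_rows.append(
                {"sample_id": sid, "patient_id": pid, "group": gname, "tissue": "blood",
                 "paired": kind == "paired"}
            )
    clinical = generate_clinical(
        config, [(p["patient_id"], p["group"]) for p in layout]
    )
    all_keys = sorted(
        {c.amino_acid_seq for r in repertoires for c in r.clones if c.is_productive}
    )
    epitope_db, db_truth = generate_epitope_db(config, all_keys)
    truth["epitope_db"] = db_truth
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "patient_id", "group", "tissue", "paired"]
    )
    return SyntheticCohort(
        config=config,
        repertoires=repertoires,
        clinical=clinical,
        epitope_db=epitope_db,
        manifest=manifest,
        truth=truth,
    )


def write_cohort(
    cohort: SyntheticCohort, out_dir: str | Path, dialect: str = "normalized"
) -> Path:
    """Write a cohort to disk: repertoire TSVs, clinical CSV, epitope TSV.

    The manifest lists every repertoire file with its SHA-256 checksum
    and dialect; ground-truth sidecars (planted shared clones per pair,
    annotated keys, the config itself) go under ``truth/``.
    """
    out = Path(out_dir)
    rep_dir = out / "repertoires"
    truth_dir = out / "truth"
    rep_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    writer = DIALECT_WRITERS[dialect]
    rows = []
    by_id = {r.sample_id: r for r in cohort.repertoires}
    for _, m in cohort.manifest.iterrows():
        rep = by_id[m["sample_id"]]
        fname = f"{rep.sample_id}.tsv"
        fpath = rep_dir / fname
        writer(rep, fpath)
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        rows.append(
            {
                "sample_id": rep.sample_id,
                "patient_id": m["patient_id"],
                "group": m["group"],
                "tissue": m["tissue"],
                "paired": bool(m["paired"]),
                "path": f"repertoires/{fname}",
                "dialect": dialect,
                "total_templates": rep.total_templates,
                "productive_templates": rep.productive_templates,
                "sha256": digest,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    write_clinical(cohort.clinical, out / "clinical.csv")
    write_epitope_db(cohort.epitope_db, out / "epitope_db.tsv")
    with open(truth_dir / "config.json", "w") as fh:
        json.dump(cohort.config.to_dict(), fh, indent=2, sort_keys=True)
    shared_rows = []
    for sid, t in sorted(cohort.truth["samples"].items()):
        if "omega" in t:
            for key in t["incidental_shared"]:
                shared_rows.append(
                    {"sample_id": sid, "paired_tumor": t["paired_tumor"], "key": key,
                     "source": "incidental"}
                )
            for key in t["injected_shared"]:
                shared_rows.append(
                    {"sample_id": sid, "paired_tumor": t["paired_tumor"], "key": key,
                     "source": "injected"}
                )
    pd.DataFrame(
        shared_rows, columns=["sample_id", "paired_tumor", "key", "source"]
    ).to_csv(truth_dir / "paired_shared_keys.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"key": cohort.truth["epitope_db"]["annotated_keys"]}
    ).to_csv(truth_dir / "annotated_keys.tsv", sep="\t", index=False)
    return out
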