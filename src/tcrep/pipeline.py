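"""End-to-end analysis pipeline: cohort directory in, report tables out.

The pipeline consumes a cohort directory (a ``manifest.tsv`` listing
per-sample repertoire files with their dialect, a ``clinical.csv`` and an
``epitope_db.tsv``) and emits TSV tables for every analysis stage:

ingest/QC -> downsampled clonality + expansion profiles -> group
contrasts -> overlap/Venn/publicity/exclusive-shared -> paired
tumor-blood overlap -> epitope annotation -> survival models.

Every stage is a pure function of (inputs, config); every output table
carries the run-config hash in a leading comment line, and reruns with
the same configuration are byte-identical.  Stages are independently
runnable (each checks for the upstream tables it needs and names the
missing prerequisite), which is what the command-line subcommands wrap.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clonality as cl
from . import overlap as ov
from .annotation import annotate, load_epitope_db, species_contrast
from .io import qc_filter, read_any, read_clinical
from .models import (
    ClinicalRecord,
    Group,
    Repertoire,
    TcrepError,
    Tissue,
)
from .stats import (
    GroupComparison,
    bh_adjust,
    cox_fit,
    km_curve,
    kruskal_wallis,
    median_dichotomize,
    pairwise_wilcoxon,
    spearman,
    wilcoxon_rank_sum,
)

logger = logging.getLogger(__name__)

_METRICS = (
    "simpson_clonality",
    "max_productive_frequency",
    "unique_productive_rearrangements",
    "total_productive_templates",
)

_HIV_POS = (Group.HIV_POS_ART_NAIVE.value, Group.HIV_POS_ART_EXP.value)


class MissingStageError(TcrepError):
    """An upstream table is missing; the message names the prerequisite."""


@dataclass
class RunConfig:
    """Pipeline configuration; every knob has a printed default."""

    cohort_dir: str
    out_dir: str
    qc_min_productive: int = 100
    depth: str | int = "auto"
    iterations: int = 100
    publicity_min_samples: int = 5
    exclusive_min_samples: int = 2
    denominator_mode: str = "all_tcrs"
    wilcoxon_exact_threshold: int = 10
    master_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        params = {k: v for k, v in self.to_dict().items()
                  if k not in ("cohort_dir", "out_dir")}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _write(df: pd.DataFrame, path: Path, chash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_stage(path: Path, stage: str) -> pd.DataFrame:
    if not path.exists():
        raise MissingStageError(
            f"{path.name} not found in {path.parent}; run the `{stage}` stage first"
        )
    return pd.read_csv(path, sep="\t", comment="#")


def load_cohort(cohort_dir: str | Path) -> tuple[list[Repertoire], pd.DataFrame]:
    """Read every repertoire listed in the cohort manifest."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise MissingStageError(
            f"manifest.tsv not found in {cohort_dir}; is this a cohort directory?"
        )
    manifest = pd.read_csv(manifest_path, sep="\t")
    reps = []
    for _, m in manifest.iterrows():
        reps.append(
            read_any(
                cohort_dir / m["path"],
                sample_id=m["sample_id"],
                tissue=m["tissue"],
                dialect=m.get("dialect", "normalized"),
            )
        )
    return reps, manifest


def _groups_map(manifest: pd.DataFrame) -> dict[str, str]:
    return dict(zip(manifest["sample_id"], manifest["group"]))


def _patients_map(manifest: pd.DataFrame) -> dict[str, str]:
    return dict(zip(manifest["sample_id"], manifest["patient_id"]))


# ---------------------------------------------------------------------------
# Stages


def stage_qc(cfg: RunConfig) -> pd.DataFrame:
    """Ingest and QC: partition samples at the productive-template threshold."""
    reps, manifest = load_cohort(cfg.cohort_dir)
    passed, _ = qc_filter(reps, cfg.qc_min_productive)
    passed_ids = {r.sample_id for r in passed}
    rows = []
    by_id = {r.sample_id: r for r in reps}
    for _, m in manifest.iterrows():
        rep = by_id[m["sample_id"]]
        rows.append(
            {
                "sample_id": rep.sample_id,
                "patient_id": m["patient_id"],
                "group": m["group"],
                "tissue": m["tissue"],
                "paired": bool(m["paired"]),
                "total_templates": rep.total_templates,
                "productive_templates": rep.productive_templates,
                "unique_productive_rearrangements": cl.unique_productive_rearrangements(rep),
                "qc_pass": rep.sample_id in passed_ids,
            }
        )
    df = pd.DataFrame(rows)
    _write(df, Path(cfg.out_dir) / "qc.tsv", cfg.config_hash())
    return df


def stage_clonality(cfg: RunConfig) -> pd.DataFrame:
    """Downsampled clonality metrics on QC-passing samples.

    The rarefaction depth is the smallest productive-template count among
    QC-passing samples when ``depth`` is "auto"; expansion-size profiles
    are computed for *all* samples without downsampling.
    """
    qc = _read_stage(Path(cfg.out_dir) / "qc.tsv", "qc")
    reps, manifest = load_cohort(cfg.cohort_dir)
    by_id = {r.sample_id: r for r in reps}
    passing = [by_id[s] for s in qc[qc["qc_pass"]]["sample_id"]]
    if not passing:
        raise TcrepError(
            f"qc stage left no samples above {cfg.qc_min_productive} productive "
            f"templates; nothing to downsample"
        )
    depth = cl.auto_depth(passing) if cfg.depth == "auto" else int(cfg.depth)
    for rep in passing:
        if rep.productive_templates < depth:
            raise TcrepError(
                f"qc stage: sample {rep.sample_id} has {rep.productive_templates} "
                f"productive templates, below the requested depth {depth}"
            )
    meta = qc.set_index("sample_id")
    rows = []
    for rep in passing:
        ds = cl.downsampled_metrics(
            rep, depth=depth, iterations=cfg.iterations, seed=cfg.master_seed
        )
        plain = cl.plain_metrics(rep)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "patient_id": meta.loc[rep.sample_id, "patient_id"],
                "group": meta.loc[rep.sample_id, "group"],
                "tissue": meta.loc[rep.sample_id, "tissue"],
                "depth": depth,
                "iterations": cfg.iterations,
                "seed": cfg.master_seed,
                "ds_simpson_clonality": ds.simpson_clonality,
                "ds_max_productive_frequency": ds.max_productive_frequency,
                "ds_unique_productive_rearrangements": ds.unique_productive_rearrangements,
                "simpson_clonality": plain.simpson_clonality,
                "max_productive_frequency": plain.max_productive_frequency,
                "unique_productive_rearrangements": plain.unique_productive_rearrangements,
                "total_productive_templates": plain.total_productive_templates,
            }
        )
    df = pd.DataFrame(rows)
    _write(df, Path(cfg.out_dir) / "clonality.tsv", cfg.config_hash())

    # expansion profiles: all samples, observed frequencies, no downsampling
    exp_rows = []
    for rep in reps:
        if rep.productive_templates == 0:
            continue
        profile = cl.expansion_profile(cl.clone_frequencies(rep))
        row = {
            "sample_id": rep.sample_id,
            "group": meta.loc[rep.sample_id, "group"],
            "tissue": meta.loc[rep.sample_id, "tissue"],
        }
        row.update(profile.proportions)
        exp_rows.append(row)
    _write(pd.DataFrame(exp_rows), Path(cfg.out_dir) / "expansion.tsv", cfg.config_hash())
    return df


def _comparison_rows(
    context: str, comps: Sequence[GroupComparison]
) -> list[dict]:
    rows = []
    for c in comps:
        rows.append(
            {
                "context": context,
                "variable": c.variable,
                "test": c.test,
                "group_a": c.groups[0],
                "group_b": c.groups[-1] if len(c.groups) == 2 else "",
                "statistic": c.statistic,
                "p_value": c.p_value,
                "p_adjusted": c.p_adjusted if c.p_adjusted is not None else np.nan,
                "fold_change": c.fold_change if c.fold_change is not None else np.nan,
                "note": c.note,
            }
        )
    return rows


def stage_stats(cfg: RunConfig) -> pd.DataFrame:
    """Group contrasts of clonality metrics and expansion-bin proportions.

    Per tissue: Kruskal-Wallis across HIV/ART groups for each downsampled
    metric with BH adjustment across the metric family, plus pairwise
    rank-sum tests with median fold-changes.  Between tissues: rank-sum
    tests on the downsampled metrics and on each expansion bin.
    """
    out = Path(cfg.out_dir)
    clon = _read_stage(out / "clonality.tsv", "clonality")
    expn = _read_stage(out / "expansion.tsv", "clonality")
    rows: list[dict] = []

    ds_cols = {
        "simpson_clonality": "ds_simpson_clonality",
        "max_productive_frequency": "ds_max_productive_frequency",
        "unique_productive_rearrangements": "ds_unique_productive_rearrangements",
        "total_productive_templates": "total_productive_templates",
    }

    # tissue contrast (downsampled metrics, QC-passing samples)
    tumor = clon[clon["tissue"] == "tumor"]
    blood = clon[clon["tissue"] == "blood"]
    if len(tumor) and len(blood):
        for metric, col in ds_cols.items():
            comp = wilcoxon_rank_sum(
                blood[col], tumor[col], cfg.wilcoxon_exact_threshold,
                variable=metric, groups=("blood", "tumor"),
            )
            med_t = float(tumor[col].median())
            fold = float(blood[col].median()) / med_t if med_t else np.nan
            row = _comparison_rows("tissue", [comp])[0]
            row["fold_change"] = fold
            rows.append(row)

    # per-tissue group comparisons
    for tissue, sub in clon.groupby("tissue"):
        values_by_metric = {}
        for metric, col in ds_cols.items():
            values_by_metric[metric] = {
                g: grp[col].tolist() for g, grp in sub.groupby("group") if len(grp) > 0
            }
        kw_ps = []
        kw_comps = []
        for metric in ds_cols:
            vals = values_by_metric[metric]
            if len([g for g in vals if len(vals[g]) > 0]) < 2:
                continue
            comp = kruskal_wallis(vals, variable=metric)
            kw_comps.append(comp)
            kw_ps.append(comp.p_value)
        adj = bh_adjust(kw_ps)
        for comp, pa in zip(kw_comps, adj):
            row = _comparison_rows(f"{tissue}:group", [comp])[0]
            row["p_adjusted"] = pa
            rows.append(row)
        for metric in ds_cols:
            vals = {g: v for g, v in values_by_metric[metric].items() if len(v) >= 2}
            if len(vals) >= 2:
                rows.extend(
                    _comparison_rows(
                        f"{tissue}:group",
                        pairwise_wilcoxon(vals, cfg.wilcoxon_exact_threshold, metric),
                    )
                )

    # expansion bins: tissue contrast and per-tissue group contrasts
    for bin_name in cl.BIN_NAMES:
        t = expn[expn["tissue"] == "tumor"][bin_name]
        b = expn[expn["tissue"] == "blood"][bin_name]
        if len(t) >= 2 and len(b) >= 2:
            comp = wilcoxon_rank_sum(
                b, t, cfg.wilcoxon_exact_threshold,
                variable=f"expansion[{bin_name}]", groups=("blood", "tumor"),
            )
            rows.extend(_comparison_rows("tissue", [comp]))
    for tissue, sub in expn.groupby("tissue"):
        for bin_name in cl.BIN_NAMES:
            vals = {g: grp[bin_name].tolist() for g, grp in sub.groupby("group") if len(grp) >= 2}
            if len(vals) >= 2:
                rows.extend(
                    _comparison_rows(
                        f"{tissue}:group",
                        pairwise_wilcoxon(
                            vals, cfg.wilcoxon_exact_threshold, f"expansion[{bin_name}]"
                        ),
                    )
                )
                rows.extend(
                    _comparison_rows(
                        f"{tissue}:group",
                        [kruskal_wallis(vals, variable=f"expansion[{bin_name}]")],
                    )
                )
    df = pd.DataFrame(rows)
    _write(df, out / "contrasts_clonality.tsv", cfg.config_hash())
    return df


def stage_overlap(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """All clone-sharing analyses; all samples, amino-acid keys, no downsampling."""
    out = Path(cfg.out_dir)
    reps, manifest = load_cohort(cfg.cohort_dir)
    groups = _groups_map(manifest)
    patients = _patients_map(manifest)
    chash = cfg.config_hash()
    results: dict[str, pd.DataFrame] = {}

    for tissue in ("tumor", "blood"):
        cohort = [r for r in reps if r.tissue.value == tissue and ov.to_clone_set(r)]
        if len(cohort) < 2:
            continue
        matrix = ov.overlap_matrix(cohort)
        mdf = matrix.to_frame().reset_index().rename(columns={"index": "sample_id"})
        _write(mdf, out / f"overlap_matrix_{tissue}.tsv", chash)
        results[f"matrix_{tissue}"] = mdf

        contrast = ov.group_contrast(matrix, groups, Group.HIV_POS_ART_NAIVE)
        crows = [
            {"reference": Group.HIV_POS_ART_NAIVE.value, "other_group": g, "overlap": v}
            for g, vals in sorted(contrast.items())
            for v in vals
        ]
        cdf = pd.DataFrame(crows, columns=["reference", "other_group", "overlap"])
        _write(cdf, out / f"overlap_vs_naive_{tissue}.tsv", chash)
        results[f"contrast_{tissue}"] = cdf

        venn = ov.venn_partition(cohort, groups)
        vdf = pd.DataFrame(
            [
                {
                    "region": "+".join(region),
                    "count": count,
                    "percent": 100.0 * count / venn.total if venn.total else 0.0,
                }
                for region, count in sorted(venn.region_counts.items())
            ]
        )
        _write(vdf, out / f"venn_{tissue}.tsv", chash)
        results[f"venn_{tissue}"] = vdf

        pub = ov.publicity(cohort, cfg.publicity_min_samples, groups)
        pdf = pd.DataFrame(
            [
                {
                    "key": r.key,
                    "sample_count": r.sample_count,
                    "sample_ids": ";".join(r.sample_ids),
                    **{f"n_{g}": r.group_counts.get(g, 0) for g in sorted({groups[s] for s in groups})},
                }
                for r in pub
            ],
            columns=["key", "sample_count", "sample_ids"]
            + [f"n_{g}" for g in sorted(set(groups.values()))],
        )
        _write(pdf, out / f"publicity_{tissue}.tsv", chash)
        results[f"publicity_{tissue}"] = pdf

        excl = ov.exclusive_shared(
            cohort, groups, _HIV_POS, cfg.exclusive_min_samples
        )
        edf = pd.DataFrame(
            [
                {"partition": "+".join(combo), "count": len(keys)}
                for combo, keys in sorted(excl.partitions.items())
            ]
        )
        _write(edf, out / f"exclusive_hivpos_{tissue}.tsv", chash)
        _write(
            excl.sample_frequencies,
            out / f"exclusive_hivpos_freq_{tissue}.tsv",
            chash,
        )
        results[f"exclusive_{tissue}"] = edf

    # paired tumor-blood overlap
    clinical = read_clinical(Path(cfg.cohort_dir) / "clinical.csv")
    age = {r.patient_id: r.age for r in clinical}
    pairs = ov.paired_by_patient(reps, patients)
    prows = []
    for pid, trep, brep in pairs:
        tset, bset = ov.to_clone_set(trep), ov.to_clone_set(brep)
        if not tset:
            continue
        prows.append(
            {
                "patient_id": pid,
                "group": groups[trep.sample_id],
                "age": age.get(pid, np.nan),
                "tumor_clones": len(tset),
                "blood_clones": len(bset),
                "tumor_blood_overlap": ov.tumor_blood_overlap(tset, bset),
            }
        )
    pdf = pd.DataFrame(
        prows,
        columns=["patient_id", "group", "age", "tumor_clones", "blood_clones",
                 "tumor_blood_overlap"],
    )
    _write(pdf, out / "tumor_blood.tsv", chash)
    results["tumor_blood"] = pdf
    return results


def stage_annotate(cfg: RunConfig) -> pd.DataFrame:
    """Epitope-database annotation and per-species group contrasts."""
    out = Path(cfg.out_dir)
    reps, manifest = load_cohort(cfg.cohort_dir)
    groups = _groups_map(manifest)
    db = load_epitope_db(Path(cfg.cohort_dir) / "epitope_db.tsv")
    species = sorted(set(db.species) | {"HIV", "InfluenzaA", "CMV", "EBV"})
    rows = []
    ann_by_tissue: dict[str, list] = {"tumor": [], "blood": []}
    for rep in reps:
        keys = ov.to_clone_set(rep)
        if not keys:
            continue
        res = annotate(keys, db, cfg.denominator_mode, sample_id=rep.sample_id)
        ann_by_tissue[rep.tissue.value].append(res)
        row = {
            "sample_id": rep.sample_id,
            "group": groups[rep.sample_id],
            "tissue": rep.tissue.value,
            "n_clones": res.n_clones,
            "n_matched": res.n_matched,
            "matched_fraction": res.matched_fraction,
            "denominator_mode": res.denominator_mode,
        }
        for sp in species:
            row[f"prop_{sp}"] = res.species_proportions.get(sp, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    _write(df, out / "annotation.tsv", cfg.config_hash())

    crows = []
    for tissue, anns in ann_by_tissue.items():
        if len(anns) < 4:
            continue
        sdf = species_contrast(anns, groups)
        sdf.insert(0, "tissue", tissue)
        crows.append(sdf)
        # matched-fraction contrast across groups
        vals: dict[str, list[float]] = {}
        for a in anns:
            vals.setdefault(groups[a.sample_id], []).append(a.matched_fraction)
        vals = {g: v for g, v in vals.items() if len(v) >= 2}
        if len(vals) >= 2:
            mrows = _comparison_rows(
                f"{tissue}:matched_fraction",
                pairwise_wilcoxon(vals, cfg.wilcoxon_exact_threshold, "matched_fraction"),
            )
            mdf = pd.DataFrame(mrows)
            mdf.insert(0, "tissue", tissue)
            crows.append(mdf)
    if crows:
        cdf = pd.concat(crows, ignore_index=True)
    else:
        cdf = pd.DataFrame()
    _write(cdf, out / "contrasts_annotation.tsv", cfg.config_hash())
    return df


def _metric_by_patient(
    clon: pd.DataFrame, tissue: str, col: str, restrict_groups: set[str] | None = None
) -> dict[str, float]:
    sub = clon[clon["tissue"] == tissue]
    if restrict_groups is not None:
        sub = sub[sub["group"].isin(restrict_groups)]
    return dict(zip(sub["patient_id"], sub[col]))


def _try_cox(rows: list[dict], context: str, **kwargs) -> None:
    try:
        res = cox_fit(**kwargs)
    except ValueError as exc:
        rows.append(
            {
                "context": context,
                "endpoint": kwargs.get("endpoint"),
                "variable": kwargs.get("variable"),
                "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p_value": np.nan, "n": np.nan, "n_events": np.nan,
                "adjusted_for": ";".join(kwargs.get("adjust_for", ())),
                "converged": False,
                "note": f"skipped: {exc}",
            }
        )
        return
    rows.append(
        {
            "context": context,
            "endpoint": res.endpoint,
            "variable": res.variable,
            "hr": res.hr,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_value,
            "n": res.n,
            "n_events": res.n_events,
            "adjusted_for": ";".join(res.adjusted_for),
            "converged": res.converged,
            "note": res.note,
        }
    )


def stage_survival(cfg: RunConfig) -> pd.DataFrame:
    """Survival analyses: KM curves, group HRs, biomarker and TCR screens.

    Biomarkers are dichotomized at the median of the analyzed subset.
    The per-TCR screen tests presence/absence of each public clone with
    unadjusted p < 0.05 as the discovery filter; discovered clones are
    refit with HIV/ART status, age, stage, ECOG and LDH adjustment.
    """
    out = Path(cfg.out_dir)
    clon = _read_stage(out / "clonality.tsv", "clonality")
    tb = _read_stage(out / "tumor_blood.tsv", "overlap")
    clinical = read_clinical(Path(cfg.cohort_dir) / "clinical.csv")
    chash = cfg.config_hash()

    # Kaplan-Meier curves by HIV/ART group and by HIV status
    strata_group = {r.patient_id: r.group.value for r in clinical}
    km = km_curve(clinical, "OS", strata_group)
    km_rows = []
    for label, stratum in km.items():
        for _, point in stratum.curve.iterrows():
            km_rows.append(
                {"stratum": label, "time": point["time"], "survival": point["survival"],
                 "n": stratum.n, "n_events": stratum.n_events,
                 "median": stratum.median if stratum.median is not None else np.nan}
            )
    _write(pd.DataFrame(km_rows), out / "km_os_group.tsv", chash)

    rows: list[dict] = []
    for endpoint in ("OS", "PFS"):
        # group effects vs the ART-experienced baseline, and HIV status
        for var in ("group_art_naive", "group_hiv_neg", "hiv_pos"):
            _try_cox(rows, "group", records=clinical, endpoint=endpoint, variable=var)

        # clonality biomarkers (median dichotomized within analyzed subset)
        specs = [
            ("tumor_simpson_all", "tumor", "ds_simpson_clonality", None, ()),
            ("tumor_simpson_all_adj", "tumor", "ds_simpson_clonality", None, ("age", "group")),
            ("tumor_simpson_hivpos", "tumor", "ds_simpson_clonality", set(_HIV_POS), ()),
            ("tumor_maxfreq_hivpos", "tumor", "ds_max_productive_frequency", set(_HIV_POS), ()),
            ("tumor_simpson_hivneg", "tumor", "ds_simpson_clonality", {Group.HIV_NEG.value}, ()),
            ("blood_unique_all", "blood", "ds_unique_productive_rearrangements", None, ()),
            ("blood_unique_all_adj", "blood", "ds_unique_productive_rearrangements", None,
             ("age", "group")),
        ]
        for name, tissue, col, restrict, adjust in specs:
            values = _metric_by_patient(clon, tissue, col, restrict)
            if len(values) < 4 or len(set(values.values())) < 2:
                continue
            binary = median_dichotomize(values)
            recs = [r for r in clinical if r.patient_id in binary]
            _try_cox(
                rows, name, records=recs, endpoint=endpoint, variable=f"{name}_high",
                adjust_for=adjust, values={k: v for k, v in binary.items()},
            )

        # tumor-blood overlap biomarker
        if len(tb) >= 4 and tb["tumor_blood_overlap"].nunique() > 1:
            values = dict(zip(tb["patient_id"], tb["tumor_blood_overlap"]))
            binary = median_dichotomize(values)
            recs = [r for r in clinical if r.patient_id in binary]
            _try_cox(rows, "tumor_blood_overlap", records=recs, endpoint=endpoint,
                     variable="tb_overlap_high", values=binary)
            _try_cox(rows, "tumor_blood_overlap_adj", records=recs, endpoint=endpoint,
                     variable="tb_overlap_high", adjust_for=("age", "group"),
                     values=binary)

    # association of tumor-blood overlap with age
    if len(tb) >= 3:
        sp = spearman(tb["age"], tb["tumor_blood_overlap"], variable="tb_overlap_vs_age")
        rows.append(
            {"context": "tumor_blood_overlap", "endpoint": "", "variable": "spearman_age",
             "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": sp.p_value,
             "n": len(tb), "n_events": np.nan, "adjusted_for": "",
             "converged": True, "note": f"rho={sp.statistic:.4f}"}
        )

    df = pd.DataFrame(rows)
    _write(df, out / "survival_cox.tsv", chash)

    # per-TCR survival screen among public clones
    screen_rows: list[dict] = []
    patients_with: dict[str, set[str]] = {}
    qc = _read_stage(out / "qc.tsv", "qc")
    for tissue in ("tumor", "blood"):
        pub_path = out / f"publicity_{tissue}.tsv"
        if not pub_path.exists():
            continue
        pub = pd.read_csv(pub_path, sep="\t", comment="#")
        sample_to_patient = dict(zip(qc["sample_id"], qc["patient_id"]))
        tissue_patients = set(qc[qc["tissue"] == tissue]["patient_id"])
        recs = [r for r in clinical if r.patient_id in tissue_patients]
        for _, p in pub.iterrows():
            carriers = {sample_to_patient[s] for s in str(p["sample_ids"]).split(";")}
            presence = {r.patient_id: 1.0 if r.patient_id in carriers else 0.0 for r in recs}
            for endpoint in ("OS", "PFS"):
                try:
                    res = cox_fit(recs, endpoint, f"tcr_present", values=presence)
                except ValueError:
                    continue
                screen_rows.append(
                    {
                        "tissue": tissue,
                        "key": p["key"],
                        "sample_count": p["sample_count"],
                        "endpoint": endpoint,
                        "hr": res.hr,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "converged": res.converged,
                        "significant": bool(res.p_value < 0.05 and res.converged),
                    }
                )
    screen = pd.DataFrame(
        screen_rows,
        columns=["tissue", "key", "sample_count", "endpoint", "hr", "ci_low",
                 "ci_high", "p_value", "converged", "significant"],
    )
    # adjusted refit of discovered clones
    adj_rows: list[dict] = []
    if len(screen):
        hits = screen[screen["significant"]]
        sample_to_patient = dict(zip(qc["sample_id"], qc["patient_id"]))
        for _, h in hits.iterrows():
            pub = pd.read_csv(out / f"publicity_{h['tissue']}.tsv", sep="\t", comment="#")
            match = pub[pub["key"] == h["key"]].iloc[0]
            carriers = {sample_to_patient[s] for s in str(match["sample_ids"]).split(";")}
            tissue_patients = set(qc[qc["tissue"] == h["tissue"]]["patient_id"])
            recs = [r for r in clinical if r.patient_id in tissue_patients]
            presence = {r.patient_id: 1.0 if r.patient_id in carriers else 0.0 for r in recs}
            try:
                res = cox_fit(
                    recs, h["endpoint"], "tcr_present",
                    adjust_for=("group", "age", "stage_gt2", "ecog", "ldh"),
                    values=presence,
                )
                adj_rows.append(
                    {"key": h["key"], "endpoint": h["endpoint"],
                     "hr_adjusted": res.hr, "p_adjusted_model": res.p_value,
                     "adjusted_converged": res.converged}
                )
            except ValueError:
                continue
    if adj_rows:
        screen = screen.merge(pd.DataFrame(adj_rows), on=["key", "endpoint"], how="left")
    _write(screen, out / "tcr_screen.tsv", chash)
    return df


def stage_report(cfg: RunConfig) -> Path:
    """Collate a markdown summary of the run."""
    out = Path(cfg.out_dir)
    qc = _read_stage(out / "qc.tsv", "qc")
    lines = [
        "# Repertoire analysis report",
        "",
        f"- config hash: `{cfg.config_hash()}`",
        f"- master seed: {cfg.master_seed}",
        "",
        "## Sample attrition",
        "",
    ]
    for tissue, sub in qc.groupby("tissue"):
        lines.append(
            f"- {tissue}: {len(sub)} sequenced, {int(sub['qc_pass'].sum())} passed QC "
            f"(> {cfg.qc_min_productive} productive templates)"
        )
    clon_path = out / "clonality.tsv"
    if clon_path.exists():
        clon = pd.read_csv(clon_path, sep="\t", comment="#")
        if len(clon):
            lines += ["", "## Clonality (downsampled)", ""]
            lines.append(f"- rarefaction depth: {int(clon['depth'].iloc[0])} productive templates, "
                         f"{int(clon['iterations'].iloc[0])} iterations")
            for (tissue, group), sub in clon.groupby(["tissue", "group"]):
                lines.append(
                    f"- {tissue}/{group}: median Simpson clonality "
                    f"{sub['ds_simpson_clonality'].median():.4f} (n={len(sub)})"
                )
    contrasts_path = out / "contrasts_clonality.tsv"
    if contrasts_path.exists():
        con = pd.read_csv(contrasts_path, sep="\t", comment="#")
        sig = con[con["p_value"] < 0.05]
        lines += ["", "## Significant contrasts (raw p < 0.05)", ""]
        for _, c in sig.iterrows():
            fold = f", fold={c['fold_change']:.2f}" if np.isfinite(c.get("fold_change", np.nan)) else ""
            lines.append(
                f"- {c['context']} {c['variable']} [{c['test']}] "
                f"{c['group_a']} vs {c['group_b']}: p={c['p_value']:.4g}{fold}"
            )
    tb_path = out / "tumor_blood.tsv"
    if tb_path.exists():
        tb = pd.read_csv(tb_path, sep="\t", comment="#")
        if len(tb):
            lines += ["", "## Tumor-blood overlap", ""]
            for group, sub in tb.groupby("group"):
                lines.append(
                    f"- {group}: median overlap {sub['tumor_blood_overlap'].median():.4f} "
                    f"(n={len(sub)})"
                )
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


STAGES = ("qc", "clonality", "stats", "overlap", "annotate", "survival", "report")


def run_all(cfg: RunConfig) -> dict[str, object]:
    """Run every stage in order; deterministic given the configuration."""
    out: dict[str, object] = {}
    out["qc"] = stage_qc(cfg)
    out["clonality"] = stage_clonality(cfg)
    out["stats"] = stage_stats(cfg)
    out["overlap"] = stage_overlap(cfg)
    out["annotate"] = stage_annotate(cfg)
    out["survival"] = stage_survival(cfg)
    out["report"] = stage_report(cfg)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": list(STAGES),
    }
    with open(Path(cfg.out_dir) / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
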