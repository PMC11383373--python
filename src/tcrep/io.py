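"""Reading and writing rearrangement tables, clinical tables and QC.

Two on-disk dialects are supported and normalized to :class:`Repertoire`:

* an immunoSEQ-export-style TSV (``nucleotide`` / ``aminoAcid`` /
  ``count (templates/reads)`` / ``sequenceStatus``); column names vary
  across platform versions, so the mapping is configurable;
* an AIRR Rearrangement TSV (``junction`` / ``junction_aa`` /
  ``duplicate_count`` / ``productive``, optionally ``stop_codon``).

On ingest, clone identity is the CDR3 nucleotide sequence: duplicate
nucleotide rows are merged by summing template counts, which makes
"unique productive rearrangements" well defined downstream.  Rows with a
template count of zero are dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import (
    CLINICAL_COVARIATES,
    ClinicalRecord,
    CloneRecord,
    FormatError,
    FrameType,
    Group,
    ParseError,
    Repertoire,
    Tissue,
    as_group,
    as_tissue,
)

IMMUNOSEQ_COLUMNS: dict[str, str] = {
    "nucleotide_seq": "nucleotide",
    "amino_acid_seq": "aminoAcid",
    "templates": "count (templates/reads)",
    "frame_type": "sequenceStatus",
}

AIRR_COLUMNS: dict[str, str] = {
    "nucleotide_seq": "junction",
    "amino_acid_seq": "junction_aa",
    "templates": "duplicate_count",
    "productive": "productive",
    "stop_codon": "stop_codon",
}

# Case-insensitive frame-status vocabulary; unrecognized values raise.
_FRAME_ALIASES: dict[str, FrameType] = {
    "in": FrameType.IN_FRAME,
    "in_frame": FrameType.IN_FRAME,
    "inframe": FrameType.IN_FRAME,
    "productive": FrameType.IN_FRAME,
    "out": FrameType.OUT_OF_FRAME,
    "out_of_frame": FrameType.OUT_OF_FRAME,
    "outofframe": FrameType.OUT_OF_FRAME,
    "stop": FrameType.HAS_STOP,
    "has_stop": FrameType.HAS_STOP,
    "stopcodon": FrameType.HAS_STOP,
}

_IMMUNOSEQ_FRAME_LABEL = {
    FrameType.IN_FRAME: "In",
    FrameType.OUT_OF_FRAME: "Out",
    FrameType.HAS_STOP: "Stop",
}

_TRUE = {"t", "true", "1"}
_FALSE = {"f", "false", "0"}


def parse_frame(value: str) -> FrameType:
    key = str(value).strip().lower().replace(" ", "").replace("-", "_")
    key = key.replace("__", "_")
    if key in _FRAME_ALIASES:
        return _FRAME_ALIASES[key]
    key2 = key.replace("_", "")
    if key2 in _FRAME_ALIASES:
        return _FRAME_ALIASES[key2]
    raise ParseError(f"unrecognized frame status {value!r}")


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")


def _require(df: pd.DataFrame, required: Mapping[str, str], path: str | Path) -> None:
    missing = [col for col in required.values() if col not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_templates(raw: str, row: int, path: str | Path) -> int:
    text = str(raw).strip()
    try:
        value = int(text)
    except ValueError:
        try:
            f = float(text)
        except ValueError:
            raise ParseError(
                f"{path}: non-integer template count {raw!r} at data row {row}"
            ) from None
        if not f.is_integer():
            raise ParseError(
                f"{path}: non-integer template count {raw!r} at data row {row}"
            )
        value = int(f)
    if value < 0:
        raise ParseError(f"{path}: negative template count {value} at data row {row}")
    return value


def _merge_clones(
    rows: Iterable[tuple[str, str, int, FrameType]]
) -> list[CloneRecord]:
    """Merge duplicate nucleotide rows by summing templates (first aa/frame wins)."""
    merged: dict[str, list] = {}
    order: list[str] = []
    for nt, aa, templates, frame in rows:
        if templates == 0:
            continue
        if nt in merged:
            merged[nt][2] += templates
        else:
            merged[nt] = [nt, aa, templates, frame]
            order.append(nt)
    return [
        CloneRecord(
            nucleotide_seq=merged[nt][0],
            amino_acid_seq=merged[nt][1],
            templates=merged[nt][2],
            frame_type=merged[nt][3],
        )
        for nt in order
    ]


def read_immunoseq(
    path: str | Path,
    sample_id: str,
    tissue: str | Tissue,
    columns: Mapping[str, str] | None = None,
) -> Repertoire:
    """Read an immunoSEQ-style rearrangement TSV into a :class:`Repertoire`."""
    colmap = dict(IMMUNOSEQ_COLUMNS)
    if columns:
        colmap.update(columns)
    df = _read_table(path)
    _require(df, colmap, path)
    rows = []
    for i in range(len(df)):
        nt = str(df[colmap["nucleotide_seq"]].iat[i]).strip()
        aa = str(df[colmap["amino_acid_seq"]].iat[i]).strip()
        templates = _parse_templates(df[colmap["templates"]].iat[i], i + 1, path)
        frame = parse_frame(df[colmap["frame_type"]].iat[i])
        if frame is not FrameType.IN_FRAME:
            aa = ""
        rows.append((nt, aa, templates, frame))
    return Repertoire(sample_id=sample_id, tissue=as_tissue(tissue), clones=_merge_clones(rows))


def read_airr(
    path: str | Path,
    sample_id: str,
    tissue: str | Tissue,
    columns: Mapping[str, str] | None = None,
) -> Repertoire:
    """Read an AIRR Rearrangement TSV.

    ``productive`` T/F maps to in-frame / non-productive; a ``stop_codon``
    column, when present, distinguishes stop-containing from out-of-frame
    rearrangements.  A missing ``duplicate_count`` column means one
    template per row.
    """
    colmap = dict(AIRR_COLUMNS)
    if columns:
        colmap.update(columns)
    df = _read_table(path)
    mandatory = {k: v for k, v in colmap.items() if k in ("nucleotide_seq", "amino_acid_seq", "productive")}
    _require(df, mandatory, path)
    has_count = colmap["templates"] in df.columns
    has_stop = colmap["stop_codon"] in df.columns
    rows = []
    for i in range(len(df)):
        row_no = i + 1
        nt = str(df[colmap["nucleotide_seq"]].iat[i]).strip()
        aa = str(df[colmap["amino_acid_seq"]].iat[i]).strip()
        templates = (
            _parse_templates(df[colmap["templates"]].iat[i], row_no, path) if has_count else 1
        )
        prod_raw = str(df[colmap["productive"]].iat[i]).strip().lower()
        if prod_raw in _TRUE:
            frame = FrameType.IN_FRAME
        elif prod_raw in _FALSE:
            frame = FrameType.OUT_OF_FRAME
            if has_stop and str(df[colmap["stop_codon"]].iat[i]).strip().lower() in _TRUE:
                frame = FrameType.HAS_STOP
            aa = ""
        else:
            raise ParseError(
                f"{path}: unrecognized productive flag "
                f"{df[colmap['productive']].iat[i]!r} at data row {row_no}"
            )
        rows.append((nt, aa, templates, frame))
    return Repertoire(sample_id=sample_id, tissue=as_tissue(tissue), clones=_merge_clones(rows))


NORMALIZED_COLUMNS = ("nucleotide_seq", "amino_acid_seq", "templates", "frame_type")


def read_repertoire(path: str | Path, sample_id: str, tissue: str | Tissue) -> Repertoire:
    """Read the package's normalized repertoire TSV."""
    df = _read_table(path)
    missing = [c for c in NORMALIZED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    rows = []
    for i in range(len(df)):
        templates = _parse_templates(df["templates"].iat[i], i + 1, path)
        rows.append(
            (
                str(df["nucleotide_seq"].iat[i]).strip(),
                str(df["amino_acid_seq"].iat[i]).strip(),
                templates,
                parse_frame(df["frame_type"].iat[i]),
            )
        )
    return Repertoire(sample_id=sample_id, tissue=as_tissue(tissue), clones=_merge_clones(rows))


def _frame_df(rep: Repertoire) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleotide_seq": [c.nucleotide_seq for c in rep.clones],
            "amino_acid_seq": [c.amino_acid_seq for c in rep.clones],
            "templates": [c.templates for c in rep.clones],
            "frame_type": [c.frame_type.value for c in rep.clones],
        }
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    _frame_df(rep).to_csv(path, sep="\t", index=False)


def write_immunoseq(rep: Repertoire, path: str | Path) -> None:
    df = _frame_df(rep)
    df["frame_type"] = [_IMMUNOSEQ_FRAME_LABEL[c.frame_type] for c in rep.clones]
    df.columns = [
        IMMUNOSEQ_COLUMNS["nucleotide_seq"],
        IMMUNOSEQ_COLUMNS["amino_acid_seq"],
        IMMUNOSEQ_COLUMNS["templates"],
        IMMUNOSEQ_COLUMNS["frame_type"],
    ]
    df.to_csv(path, sep="\t", index=False)


def write_airr(rep: Repertoire, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "junction": [c.nucleotide_seq for c in rep.clones],
            "junction_aa": [c.amino_acid_seq for c in rep.clones],
            "duplicate_count": [c.templates for c in rep.clones],
            "productive": ["T" if c.is_productive else "F" for c in rep.clones],
            "stop_codon": ["T" if c.frame_type is FrameType.HAS_STOP else "F" for c in rep.clones],
        }
    )
    df.to_csv(path, sep="\t", index=False)


DIALECT_READERS = {
    "immunoseq": read_immunoseq,
    "airr": read_airr,
    "normalized": read_repertoire,
}

DIALECT_WRITERS = {
    "immunoseq": write_immunoseq,
    "airr": write_airr,
    "normalized": write_repertoire,
}


def read_any(path: str | Path, sample_id: str, tissue: str | Tissue, dialect: str) -> Repertoire:
    try:
        reader = DIALECT_READERS[dialect]
    except KeyError:
        raise FormatError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_READERS)}"
        ) from None
    return reader(path, sample_id, tissue)


def productive_subset(rep: Repertoire) -> Repertoire:
    """Restrict to in-frame, stop-free clones; totals recompute automatically.

    Idempotent: applying it twice equals applying it once.
    """
    return Repertoire(
        sample_id=rep.sample_id,
        tissue=rep.tissue,
        clones=[c for c in rep.clones if c.is_productive],
    )


def qc_filter(
    cohort: Sequence[Repertoire], min_productive: int = 100
) -> tuple[list[Repertoire], list[Repertoire]]:
    """Partition a cohort by the productive-template QC threshold.

    A sample passes only with *strictly more than* ``min_productive``
    productive templates.  Order is preserved within each part.
    """
    if min_productive < 0:
        raise ValueError("min_productive must be >= 0")
    passed = [r for r in cohort if r.productive_templates > min_productive]
    failed = [r for r in cohort if r.productive_templates <= min_productive]
    return passed, failed


# ---------------------------------------------------------------------------
# Clinical table I/O

_CLINICAL_FIXED = (
    "patient_id",
    "group",
    "age",
    "sex",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
)


def _parse_bool(value, where: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParseError(f"{where}: cannot parse boolean {value!r}")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CLINICAL_FIXED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in _CLINICAL_FIXED]
    records = []
    for i in range(len(df)):
        covs: dict[str, float | str | None] = {}
        for c in extra:
            raw = str(df[c].iat[i]).strip()
            if raw == "":
                covs[c] = None
            else:
                try:
                    covs[c] = float(raw)
                except ValueError:
                    covs[c] = raw
        records.append(
            ClinicalRecord(
                patient_id=str(df["patient_id"].iat[i]),
                group=as_group(str(df["group"].iat[i])),
                age=float(df["age"].iat[i]),
                sex=str(df["sex"].iat[i]),
                os_months=float(df["os_months"].iat[i]),
                os_event=_parse_bool(df["os_event"].iat[i], f"{path} row {i + 1}"),
                pfs_months=float(df["pfs_months"].iat[i]),
                pfs_event=_parse_bool(df["pfs_event"].iat[i], f"{path} row {i + 1}"),
                covariates=covs,
            )
        )
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    cov_names = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "group": r.group.value,
            "age": r.age,
            "sex": r.sex,
            "os_months": r.os_months,
            "os_event": int(r.os_event),
            "pfs_months": r.pfs_months,
            "pfs_event": int(r.pfs_event),
        }
        for k in cov_names:
            v = r.covariates.get(k)
            row[k] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
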