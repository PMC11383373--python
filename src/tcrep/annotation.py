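"""Epitope annotation of repertoires against a VDJdb-style table.

Matching is exact CDR3 amino-acid equality against the database's CDR3
column — no fuzzy or edit-distance search.  A clone with database entries
for several species counts once toward each species' numerator but only
once toward the matched fraction.  The "epitope proportion" for a species
divides the number of matching clones by either all of the sample's
clones (``all_tcrs``, the default) or only the database-matched ones
(``matched_tcrs``); both conventions are exposed because published
per-species proportions are ambiguous between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import EmptyRepertoireError, FormatError, as_group
from .stats import pairwise_wilcoxon

logger = logging.getLogger(__name__)

VDJDB_COLUMNS: dict[str, str] = {
    "cdr3_aa": "cdr3",
    "species": "antigen.species",
    "epitope": "antigen.epitope",
    "mhc_class": "mhc.class",
}

DENOMINATOR_MODES = ("all_tcrs", "matched_tcrs")


@dataclass
class EpitopeDB:
    """Deduplicated (CDR3, species, epitope) annotation table."""

    entries: pd.DataFrame  # columns: cdr3_aa, species, epitope, mhc_class

    def __post_init__(self) -> None:
        self._by_cdr3: dict[str, set[str]] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def species_by_cdr3(self) -> dict[str, set[str]]:
        if self._by_cdr3 is None:
            mapping: dict[str, set[str]] = {}
            for cdr3, species in zip(self.entries["cdr3_aa"], self.entries["species"]):
                mapping.setdefault(cdr3, set()).add(species)
            self._by_cdr3 = mapping
        return self._by_cdr3

    @property
    def species(self) -> list[str]:
        return sorted(self.entries["species"].unique())


def load_epitope_db(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> EpitopeDB:
    """Load a VDJdb-export-style TSV, deduplicating (CDR3, species, epitope)."""
    colmap = dict(VDJDB_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [colmap["cdr3_aa"], colmap["species"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame(
        {
            "cdr3_aa": df[colmap["cdr3_aa"]].str.strip(),
            "species": df[colmap["species"]].str.strip(),
            "epitope": df[colmap["epitope"]].str.strip()
            if colmap["epitope"] in df.columns
            else "",
            "mhc_class": df[colmap["mhc_class"]].str.strip()
            if colmap["mhc_class"] in df.columns
            else "",
        }
    )
    out = out.drop_duplicates(subset=["cdr3_aa", "species", "epitope"]).reset_index(drop=True)
    return EpitopeDB(entries=out)


def write_epitope_db(db: EpitopeDB, path: str | Path) -> None:
    df = db.entries.rename(
        columns={
            "cdr3_aa": VDJDB_COLUMNS["cdr3_aa"],
            "species": VDJDB_COLUMNS["species"],
            "epitope": VDJDB_COLUMNS["epitope"],
            "mhc_class": VDJDB_COLUMNS["mhc_class"],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnnotationResult:
    """Per-sample database-matched fraction and per-species proportions."""

    sample_id: str
    matched_fraction: float
    species_proportions: dict[str, float]
    denominator_mode: str
    n_clones: int
    n_matched: int

    def __post_init__(self) -> None:
        for sp, p in self.species_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"species proportion for {sp} out of [0,1]: {p}")


def annotate(
    clone_set: Iterable[str],
    db: EpitopeDB,
    denominator_mode: str = "all_tcrs",
    sample_id: str = "",
) -> AnnotationResult:
    """Annotate a sample's clone set against the database.

    ``matched_fraction`` is the share of distinct clones with any database
    entry.  Counting is at the unique-clone level, never template-weighted.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(
            f"denominator_mode must be one of {DENOMINATOR_MODES}, got {denominator_mode!r}"
        )
    keys = set(clone_set)
    if not keys:
        raise EmptyRepertoireError(f"{sample_id}: cannot annotate an empty clone set")
    lookup = db.species_by_cdr3
    matched = {k for k in keys if k in lookup}
    species_counts: dict[str, int] = {}
    for k in matched:
        for sp in lookup[k]:
            species_counts[sp] = species_counts.get(sp, 0) + 1
    denom = len(keys) if denominator_mode == "all_tcrs" else max(len(matched), 1)
    proportions = {sp: n / denom for sp, n in sorted(species_counts.items())}
    return AnnotationResult(
        sample_id=sample_id,
        matched_fraction=len(matched) / len(keys),
        species_proportions=proportions,
        denominator_mode=denominator_mode,
        n_clones=len(keys),
        n_matched=len(matched),
    )


DEFAULT_CONTRAST_SPECIES = ("HIV", "InfluenzaA", "CMV", "EBV")


def species_contrast(
    results: Sequence[AnnotationResult],
    groups: Mapping[str, str],
    species: Sequence[str] = DEFAULT_CONTRAST_SPECIES,
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of per-species proportions across groups.

    Groups with fewer than two annotated samples are flagged and skipped.
    """
    rows = []
    for sp in species:
        values: dict[str, list[float]] = {}
        for res in results:
            g = as_group(groups[res.sample_id]).value
            values.setdefault(g, []).append(res.species_proportions.get(sp, 0.0))
        usable = {g: v for g, v in values.items() if len(v) >= 2}
        skipped = sorted(set(values) - set(usable))
        for g in skipped:
            logger.warning("species %s: group %s has <2 samples; comparison skipped", sp, g)
        if len(usable) >= 2:
            for comp in pairwise_wilcoxon(usable, variable=f"proportion[{sp}]"):
                rows.append(
                    {
                        "species": sp,
                        "group_a": comp.groups[0],
                        "group_b": comp.groups[1],
                        "n_a": len(usable[comp.groups[0]]),
                        "n_b": len(usable[comp.groups[1]]),
                        "statistic": comp.statistic,
                        "p_value": comp.p_value,
                        "fold_change": comp.fold_change,
                        "skipped_groups": ";".join(skipped),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "group_a",
            "group_b",
            "n_a",
            "n_b",
            "statistic",
            "p_value",
            "fold_change",
            "skipped_groups",
        ],
    )
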