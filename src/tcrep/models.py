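"""Core domain types for bulk TCR-beta repertoire analysis.

A *repertoire* is one sample's table of TCR-beta rearrangements: each row
(clone) is a distinct CDR3 nucleotide sequence with a template count, the
number of input DNA molecules attributed to that rearrangement.  Templates
are the unit of abundance throughout; a rearrangement is *productive* when
it is in-frame with no stop codon, and only productive templates enter the
clonality and sharing analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class TcrepError(Exception):
    """Base class for package errors."""


class FormatError(TcrepError):
    """A required column or field is missing or malformed."""


class ParseError(TcrepError):
    """A value could not be parsed; the message names the offending row."""


class EmptyRepertoireError(TcrepError):
    """An operation that needs at least one productive clone got none."""


class InsufficientDepthError(TcrepError):
    """Downsampling depth exceeds the available productive templates."""


class UndefinedOverlapError(TcrepError):
    """Overlap of an empty clone set is undefined."""


class ConfigError(TcrepError):
    """Invalid simulator or pipeline configuration."""


class FrameType(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    HAS_STOP = "has_stop"


class Tissue(str, Enum):
    TUMOR = "tumor"
    BLOOD = "blood"


class Group(str, Enum):
    """HIV/ART exposure strata.

    ART-experienced means more than 6 months of antiretroviral therapy
    before study enrollment; ART-naive means 6 months or less.
    """

    HIV_NEG = "HIV_neg"
    HIV_POS_ART_NAIVE = "HIV_pos_ART_naive"
    HIV_POS_ART_EXP = "HIV_pos_ART_exp"


GROUPS = (Group.HIV_NEG, Group.HIV_POS_ART_NAIVE, Group.HIV_POS_ART_EXP)


@dataclass(frozen=True)
class CloneRecord:
    """One rearrangement: CDR3 DNA, CDR3 protein, abundance and frame status.

    ``amino_acid_seq`` is non-empty exactly when the rearrangement is
    in-frame; out-of-frame or stop-containing rearrangements carry no
    protein sequence.
    """

    nucleotide_seq: str
    amino_acid_seq: str
    templates: int
    frame_type: FrameType

    def __post_init__(self) -> None:
        if self.templates < 1:
            raise ValueError(
                f"templates must be >= 1, got {self.templates} "
                f"for {self.nucleotide_seq!r}"
            )
        in_frame = self.frame_type is FrameType.IN_FRAME
        if in_frame and not self.amino_acid_seq:
            raise ValueError(
                f"in-frame clone {self.nucleotide_seq!r} lacks an amino-acid sequence"
            )
        if not in_frame and self.amino_acid_seq:
            raise ValueError(
                f"non-productive clone {self.nucleotide_seq!r} must not carry "
                f"an amino-acid sequence"
            )

    @property
    def is_productive(self) -> bool:
        return self.frame_type is FrameType.IN_FRAME


@dataclass
class Repertoire:
    """One sample's clone table.

    Template totals are derived from the clone list, so the bookkeeping
    invariants (total = sum of counts, productive = sum over in-frame
    clones) hold by construction.
    """

    sample_id: str
    tissue: Tissue
    clones: list[CloneRecord] = field(default_factory=list)

    @property
    def total_templates(self) -> int:
        return sum(c.templates for c in self.clones)

    @property
    def productive_templates(self) -> int:
        return sum(c.templates for c in self.clones if c.is_productive)

    @property
    def productive_clones(self) -> list[CloneRecord]:
        return [c for c in self.clones if c.is_productive]

    def __len__(self) -> int:
        return len(self.clones)


#: Covariate names expected in a clinical table beyond the fixed columns.
CLINICAL_COVARIATES = (
    "ldh",
    "ecog",
    "stage_gt2",
    "ki67",
    "eber",
    "cell_of_origin",
    "hiv_viral_load",
    "cd4_count",
    "art_duration_months",
)

#: ART-duration threshold (months) separating ART-naive from ART-experienced.
ART_EXPERIENCED_MONTHS = 6.0


@dataclass
class ClinicalRecord:
    """Per-patient clinical data: group, demographics, outcomes, covariates.

    OS runs from enrollment to death or censoring; PFS to progression,
    death, or censoring, whichever comes first, so ``pfs_months`` can
    never exceed ``os_months``.
    """

    patient_id: str
    group: Group
    age: float
    sex: str
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    covariates: dict[str, float | str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.os_months < 0 or self.pfs_months < 0:
            raise ValueError(f"{self.patient_id}: negative survival time")
        if self.pfs_months > self.os_months + 1e-9:
            raise ValueError(
                f"{self.patient_id}: pfs_months ({self.pfs_months}) exceeds "
                f"os_months ({self.os_months})"
            )
        art = self.covariates.get("art_duration_months")
        if art is not None:
            art = float(art)
            if self.group is Group.HIV_POS_ART_EXP and art <= ART_EXPERIENCED_MONTHS:
                raise ValueError(
                    f"{self.patient_id}: ART-experienced requires "
                    f"> {ART_EXPERIENCED_MONTHS} months of ART, got {art}"
                )
            if self.group is Group.HIV_POS_ART_NAIVE and art > ART_EXPERIENCED_MONTHS:
                raise ValueError(
                    f"{self.patient_id}: ART-naive requires "
                    f"<= {ART_EXPERIENCED_MONTHS} months of ART, got {art}"
                )


def as_group(value: str | Group) -> Group:
    if isinstance(value, Group):
        return value
    try:
        return Group(value)
    except ValueError as exc:
        raise ValueError(
            f"unknown group {value!r}; expected one of "
            f"{[g.value for g in GROUPS]}"
        ) from exc


def as_tissue(value: str | Tissue) -> Tissue:
    if isinstance(value, Tissue):
        return value
    try:
        return Tissue(value)
    except ValueError as exc:
        raise ValueError(f"unknown tissue {value!r}; expected 'tumor' or 'blood'") from exc
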