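"""Group comparisons, multiple-testing correction and survival analysis.

Nonparametric tests follow common statistical-environment defaults: the
Wilcoxon rank-sum test is exact when both groups have at most
``exact_threshold`` observations and no ties, otherwise the normal
approximation with tie and continuity correction is used; the
Kruskal-Wallis H statistic is tie-corrected with a chi-square p-value on
k-1 degrees of freedom; Spearman correlation handles ties through
midranks.  Multiple comparisons use Benjamini-Hochberg step-up
adjustment.  Cox proportional-hazards models are fit by partial
likelihood with Efron tie handling, and survival dichotomizations split
at the median of the analyzed subset (value > median -> "high").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .models import ClinicalRecord, Group

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    groups: tuple[str, ...]
    test: str  # wilcoxon | kruskal_wallis | spearman
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    fold_change: float | None = None  # median(group A) / median(group B)
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p below raw p")


@dataclass(frozen=True)
class SurvivalResult:
    endpoint: str  # OS | PFS
    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted_for: tuple[str, ...] = ()
    converged: bool = True
    n: int = 0
    n_events: int = 0
    note: str = ""


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = 10,
    variable: str = "",
    groups: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Exact enumeration when both samples are small (<= ``exact_threshold``)
    and tie-free; otherwise the normal approximation with continuity and
    tie correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (xa.size <= exact_threshold and ya.size <= exact_threshold and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return GroupComparison(
        variable=variable,
        groups=groups,
        test="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        note=method,
    )


def pairwise_wilcoxon(
    values: Mapping[str, Sequence[float]],
    exact_threshold: int = 10,
    variable: str = "",
) -> list[GroupComparison]:
    """All unordered group pairs, with median fold-changes attached.

    ``fold_change`` is median(group A)/median(group B) in the orientation
    of the ``groups`` tuple; it is omitted (with a note) when the
    denominator median is zero.
    """
    names = sorted(values)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            comp = wilcoxon_rank_sum(
                values[a], values[b], exact_threshold, variable=variable, groups=(a, b)
            )
            med_a = float(np.median(np.asarray(values[a], dtype=float)))
            med_b = float(np.median(np.asarray(values[b], dtype=float)))
            if med_b == 0.0:
                out.append(
                    GroupComparison(
                        variable=comp.variable,
                        groups=comp.groups,
                        test=comp.test,
                        statistic=comp.statistic,
                        p_value=comp.p_value,
                        fold_change=None,
                        note=(comp.note + ";zero-median-denominator").strip(";"),
                    )
                )
            else:
                out.append(
                    GroupComparison(
                        variable=comp.variable,
                        groups=comp.groups,
                        test=comp.test,
                        statistic=comp.statistic,
                        p_value=comp.p_value,
                        fold_change=med_a / med_b,
                        note=comp.note,
                    )
                )
    return out


def kruskal_wallis(
    values: Mapping[str, Sequence[float]], variable: str = ""
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H test across all non-empty groups."""
    names = sorted(g for g in values if len(values[g]) > 0)
    if len(names) < 2:
        raise ValueError("kruskal_wallis requires at least two non-empty groups")
    samples = [np.asarray(values[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    if np.unique(pooled).size == 1:
        # degenerate case: no variation at all -> H = 0, p = 1
        return GroupComparison(
            variable=variable,
            groups=tuple(names),
            test="kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            note="degenerate:identical",
        )
    stat, p = sps.kruskal(*samples)
    return GroupComparison(
        variable=variable,
        groups=tuple(names),
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="fdr_bh")[1])


def spearman(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Spearman rank correlation with a two-sided p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("spearman requires n >= 3")
    rho, p = sps.spearmanr(xa, ya)
    return GroupComparison(
        variable=variable,
        groups=("x", "y"),
        test="spearman",
        statistic=float(rho),
        p_value=float(min(p, 1.0)) if np.isfinite(p) else 1.0,
    )


def median_dichotomize(values: Mapping[str, float]) -> dict[str, str]:
    """Split at the median of the analyzed subset: > median -> "high".

    Values exactly at the median are "low".  A set of identical values
    has no split and raises.
    """
    if not values:
        raise ValueError("median_dichotomize needs at least one value")
    arr = np.asarray(list(values.values()), dtype=float)
    if np.unique(arr).size == 1:
        raise ValueError("all values identical: median split is degenerate")
    med = float(np.median(arr))
    return {k: ("high" if v > med else "low") for k, v in values.items()}


# ---------------------------------------------------------------------------
# Survival


def records_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Numeric analysis frame: outcomes, group dummies and covariates.

    Group dummies use ART-experienced as the baseline level.
    """
    rows = []
    for r in records:
        row: dict[str, float] = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex_male": 1.0 if str(r.sex).upper().startswith("M") else 0.0,
            "os_months": r.os_months,
            "os_event": float(r.os_event),
            "pfs_months": r.pfs_months,
            "pfs_event": float(r.pfs_event),
            "group_hiv_neg": 1.0 if r.group is Group.HIV_NEG else 0.0,
            "group_art_naive": 1.0 if r.group is Group.HIV_POS_ART_NAIVE else 0.0,
            "hiv_pos": 0.0 if r.group is Group.HIV_NEG else 1.0,
        }
        for k, v in r.covariates.items():
            if isinstance(v, (int, float)) and v is not None:
                row[k] = float(v)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


_ENDPOINTS = {"OS": ("os_months", "os_event"), "PFS": ("pfs_months", "pfs_event")}

#: Columns the group adjustment expands to.
GROUP_DUMMIES = ("group_hiv_neg", "group_art_naive")


def cox_fit(
    records: Sequence[ClinicalRecord],
    endpoint: str,
    variable: str,
    adjust_for: Sequence[str] = (),
    values: Mapping[str, float] | None = None,
) -> SurvivalResult:
    """Cox proportional-hazards fit (Efron ties) for one variable.

    ``variable`` is resolved against the clinical frame, or supplied
    directly as a per-patient mapping via ``values`` (e.g. a dichotomized
    biomarker coded 0/1 or "low"/"high").  ``adjust_for`` entries name
    frame columns; the shorthand ``"group"`` expands to HIV/ART dummies.
    Non-convergence or complete separation is flagged on the result, not
    silently dropped.
    """
    if endpoint not in _ENDPOINTS:
        raise ValueError(f"endpoint must be OS or PFS, got {endpoint!r}")
    dur_col, ev_col = _ENDPOINTS[endpoint]
    df = records_frame(records)
    if values is not None:
        mapped = {}
        for pid, v in values.items():
            if isinstance(v, str):
                mapped[pid] = {"low": 0.0, "high": 1.0}[v]
            else:
                mapped[pid] = float(v)
        df[variable] = pd.Series(mapped)
        df = df[df[variable].notna()]
    if variable not in df.columns:
        raise ValueError(f"unknown variable {variable!r}")
    covs: list[str] = [variable]
    for a in adjust_for:
        if a == "group":
            covs.extend(GROUP_DUMMIES)
        else:
            covs.append(a)
    covs = list(dict.fromkeys(covs))
    use = df[[dur_col, ev_col, *covs]].dropna()
    n_events = int(use[ev_col].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")
    if use[variable].nunique() < 2:
        raise ValueError(f"variable {variable!r} does not vary")
    fitter = CoxPHFitter()
    note = ""
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(use, duration_col=dur_col, event_col=ev_col)
        msgs = [str(w.message) for w in caught if "convergence" in str(w.message).lower()
                or "separation" in str(w.message).lower() or "collinear" in str(w.message).lower()]
        if msgs:
            converged = False
            note = msgs[0].splitlines()[0][:200]
    except ConvergenceError as exc:
        return SurvivalResult(
            endpoint=endpoint,
            variable=variable,
            hr=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            adjusted_for=tuple(a for a in adjust_for),
            converged=False,
            n=len(use),
            n_events=n_events,
            note=f"ConvergenceError: {str(exc).splitlines()[0][:200]}",
        )
    summary = fitter.summary
    row = summary.loc[variable]
    return SurvivalResult(
        endpoint=endpoint,
        variable=variable,
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p_value=float(row["p"]),
        adjusted_for=tuple(a for a in adjust_for),
        converged=converged,
        n=len(use),
        n_events=n_events,
        note=note,
    )


@dataclass
class KMStratum:
    label: str
    curve: pd.DataFrame  # columns: time, survival
    median: float | None
    n: int
    n_events: int


def km_curve(
    records: Sequence[ClinicalRecord],
    endpoint: str,
    strata: Mapping[str, str] | None = None,
) -> dict[str, KMStratum]:
    """Kaplan-Meier product-limit curves per stratum.

    ``strata`` maps patient_id -> label; patients without a label are
    excluded, and empty strata are skipped with a warning.  The median is
    the first time the survival curve drops to 0.5 or below, None if it
    never does.
    """
    if endpoint not in _ENDPOINTS:
        raise ValueError(f"endpoint must be OS or PFS, got {endpoint!r}")
    dur_col, ev_col = _ENDPOINTS[endpoint]
    by_label: dict[str, list[ClinicalRecord]] = {}
    for r in records:
        if strata is None:
            label = "all"
        elif r.patient_id in strata:
            label = strata[r.patient_id]
        else:
            continue
        by_label.setdefault(label, []).append(r)
    out: dict[str, KMStratum] = {}
    for label in sorted(by_label):
        recs = by_label[label]
        if not recs:
            logger.warning("empty stratum %s skipped", label)
            continue
        durations = [getattr(r, dur_col) for r in recs]
        events = [getattr(r, ev_col) for r in recs]
        kmf = KaplanMeierFitter()
        kmf.fit(durations, events, label=label)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        med = kmf.median_survival_time_
        out[label] = KMStratum(
            label=label,
            curve=curve,
            median=None if np.isinf(med) else float(med),
            n=len(recs),
            n_events=int(sum(events)),
        )
    return out
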