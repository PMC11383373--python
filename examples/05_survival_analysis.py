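"""Relate repertoire features to clinical outcome.

Continuous biomarkers are dichotomized at the median of the analyzed
subset; hazard ratios come from Cox proportional-hazards fits and group
curves from the Kaplan-Meier estimator.
"""

from tcrep import (
    CohortConfig,
    auto_depth,
    cox_fit,
    downsampled_metrics,
    generate_cohort,
    km_curve,
    median_dichotomize,
    qc_filter,
)

cohort = generate_cohort(CohortConfig(master_seed=1))

strata = {r.patient_id: r.group.value for r in cohort.clinical}
km = km_curve(cohort.clinical, "OS", strata)
print("median overall survival by HIV/ART group:")
for label, stratum in km.items():
    med = f"{stratum.median:.1f} months" if stratum.median else "not reached"
    print(f"  {label:>22}: {med} (n={stratum.n}, events={stratum.n_events})")

res = cox_fit(cohort.clinical, "OS", "group_art_naive")
print(f"\nART-naive vs ART-experienced: HR={res.hr:.2f} "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}], p={res.p_value:.3f}")
# HR < 1 means lower hazard (longer survival) for ART-naive patients,
# mirroring the planted group effects of the simulator.

# tumor Simpson clonality as a median-split biomarker, rarefied to the
# lowest productive count among QC-passing tumors
passed, _ = qc_filter([r for r in cohort.repertoires if r.tissue.value == "tumor"])
depth = auto_depth(passed)
patient_of = dict(zip(cohort.manifest["sample_id"], cohort.manifest["patient_id"]))
values = {
    patient_of[r.sample_id]: downsampled_metrics(r, depth, 100, seed=1).simpson_clonality
    for r in passed
}
binary = median_dichotomize(values)
recs = [r for r in cohort.clinical if r.patient_id in binary]
res = cox_fit(recs, "OS", "tumor_clonality_high", values=binary)
print(f"high vs low tumor clonality: HR={res.hr:.2f} "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}], p={res.p_value:.3f} (n={res.n})")
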