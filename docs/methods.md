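# Methods

## Scope and data model

The package analyzes bulk TCR-beta repertoires: per-sample tables of
CDR3 rearrangements with template counts (one template = one input DNA
molecule, a proxy for cell count). A rearrangement is *productive* when
it is in-frame with no stop codon; only productive templates enter the
analyses. Two clone-identity conventions coexist deliberately:

* **nucleotide-level** for the clonality metrics ("unique productive
  rearrangements" counts distinct CDR3 DNA sequences, matching how
  immunoSEQ-style pipelines report diversity);
* **amino-acid-level** for all sharing analyses (overlap, Venn,
  publicity, annotation), where nucleotide variants encoding the same
  protein collapse to one clonotype.

On ingest, duplicate nucleotide rows are merged by summing template
counts, zero-count rows are dropped, and unrecognized frame labels
raise rather than coerce.

## Clonality and rarefaction

Productive Simpson clonality is `sqrt(sum p_i^2)` over productive clone
frequencies; max productive frequency is `max p_i`; unique productive
rearrangements is the count of distinct productive CDR3 DNA sequences.
The plug-in Simpson estimator is used (no singleton correction): its
value at finite depth *n* is biased upward by roughly `(1 - sum
p_i^2)/n`, which is precisely why cross-sample comparisons are made at
a single common depth.

Rarefaction draws `depth` templates **without replacement** from the
productive template multiset (a multivariate hypergeometric draw over
clones), recomputes all three metrics on the draw, and reports
arithmetic means over `iterations` (default 100). Sampling without
replacement was chosen over bootstrap resampling because it makes
`depth = total` reproduce the plain metrics exactly — that case is
special-cased so the equality is bit-exact, not merely within floating
error. The default depth is "auto": the smallest productive-template
count among QC-passing samples (QC passes on *strictly more than* 100
productive templates, so auto depth lies in 101–108 under the default
simulator, matching the shallow-tumor regime the package targets).

Per-sample random streams are derived by hashing `(master seed,
sample id)` into a `SeedSequence`, so adding samples to a cohort never
perturbs the draws of existing ones and every result is a pure function
of the configuration.

Clonal expansions are binned by the fraction of the repertoire a clone
occupies. Bins are left-open and right-closed — small (0, 1e-4], medium
(1e-4, 1e-3], large (1e-3, 1e-2], hyperexpanded (1e-2, 1] — so a clone
at exactly a printed boundary falls in the lower bin; bin proportions
are clone-frequency sums and partition the repertoire exactly.
Expansion profiles are computed on observed frequencies without
downsampling.

## Sharing statistics

Pairwise overlap is `|A ∩ B| / min(|A|, |B|)` on presence/absence clone
sets — not an abundance-weighted index. Within-reference-group overlap
distributions count each unordered pair once and exclude self-pairs.
The Venn partition assigns each distinct clonotype to the exact set of
groups whose samples carry it. Publicity records clones present in at
least `min_samples` distinct samples (default 5), sorted by carrier
count then key. "Exclusive shared" clones occur in ≥ 2 samples, all
belonging to a nominated set of groups, and are partitioned by the
sub-groups their carriers span; the per-sample summary reports, for
each carrying sample, the fraction of its distinct clonotypes in each
partition. Tumor-blood overlap is `|tumor ∩ blood| / |tumor|` per
patient — asymmetric, and invariant to blood clones absent from tumor.
If a patient somehow has several samples of one tissue, the first by
sample id is used and a warning logged.

## Epitope annotation

Annotation is exact string match of CDR3 amino-acid sequences against a
VDJdb-style table, deduplicated at (CDR3, species, epitope) level, with
no HLA restriction and no fuzzy matching. A clone with entries for
several species counts once per species but once in total toward the
matched fraction. The per-species "epitope proportion" denominator is
configurable: `all_tcrs` (default — all of the sample's distinct
clones) or `matched_tcrs` (only database-matched clones). Both are
offered because published per-species proportions are ambiguous between
the two conventions; neither is asserted as canonical. Counting is at
unique-clone level, never template-weighted.

## Statistics

* Wilcoxon rank-sum: exact enumeration when both groups have ≤ 10
  observations and no ties; otherwise the normal approximation with
  continuity and tie correction. The threshold matches common
  statistical-environment defaults.
* Kruskal–Wallis: tie-corrected H with a chi-square p on k−1 degrees of
  freedom; a fully degenerate input (all observations identical) is
  reported as H = 0, p = 1 rather than an error.
* Spearman correlation with midrank ties; two-sided p; requires n ≥ 3.
* Benjamini–Hochberg step-up adjustment, monotone and capped at 1, in
  the original order.
* Fold-changes are ratios of group medians, reported in the orientation
  of the comparison tuple, omitted with a note when the denominator
  median is zero.
* Median dichotomization: value > median → "high", values at the median
  → "low"; the median is recomputed on each analyzed subset (e.g.
  HIV-positive patients only). An all-identical input raises.
* Cox proportional-hazards fits use lifelines with Efron tie handling
  (the standard default). Non-convergence and complete-separation
  warnings are surfaced as a flagged result, never silently dropped;
  covariates that do not vary raise. The per-clonotype survival screen
  uses unadjusted p < 0.05 as its discovery filter (screening, not
  inference); discovered clones are refit with HIV/ART status, age,
  stage, ECOG and LDH adjustment.
* Kaplan–Meier medians are the first time the survival curve reaches
  0.5 or below, reported as absent when it never does.

## The synthetic cohort

The simulator generates data with the statistical structure the
analysis assumes, so planted parameters are recoverable by the pipeline
itself. It emulates a 62-patient cohort: 57 tumors (19
HIV-negative / 27 ART-experienced / 11 ART-naive), 21 bloods (7/7/7),
16 tumor-blood pairs.

**Clone sizes.** Each sample draws clone frequencies from a symmetric
Dirichlet(α) over a per-sample pool (tumor 200 clones, blood 10,000).
The Dirichlet-multinomial model was chosen over a power-law because it
has closed-form limits (uniform as α → ∞, single-clone dominance as
α·C → 0) and a single ordering knob. Default concentrations make
ART-naive tumors the most clonal stratum (tumor α: 3 / 3 / 0.3 for
HIV-negative / ART-experienced / ART-naive) and blood uniformly clonal
(α = 0.005 over the large pool). The tumor pool size of 200 was set so
that the ART-naive vs HIV-negative contrast at the rarefaction depth of
108 lands near the ~1.4-fold Simpson-clonality difference typical of
this setting; measured at depth 108 the two regimes give ≈ 0.17 vs
≈ 0.13.

**Depth.** Productive template totals are log-normal per tissue
(medians 300 tumor / 20,700 blood; σ 1.5 / 0.6 — tumor FFPE input is
highly variable, which also produces realistic QC attrition of roughly
a fifth of tumors). The total template count is the productive target
divided by the tissue's productive fraction (0.77 tumor, 0.80 blood),
and the realized productive count is binomial at that fraction; the
non-productive remainder is allocated to out-of-frame and stop-codon
clones with no amino-acid sequence.

**Sequences and sharing.** CDR3 amino-acid strings are synthetic
("C" + 8–12 random residues + "F") — biologically naive, but no
operation inspects content beyond equality. Each pool clone draws its
CDR3 from a cohort-wide public pool of 2,000 keys with a per-group
sharing probability (0.15 / 0.15 / 0.05; ART-naive repertoires are the
most private), else receives a fresh private string. Public keys are
drawn with Zipf (1/rank) weights so a head of common clones recurs in
many samples — this is what populates the ≥ 5-sample publicity records
while keeping tail keys rare. Each amino-acid clone receives one or
occasionally two nucleotide variants (probability 0.3 for splittable
clones), so nucleotide-level unique counts exceed amino-acid-level
ones, as in real exports.

**Paired overlap.** For a paired patient the blood repertoire is
generated independently, then enough observed tumor clones are grafted
onto blood clones (relabeling the amino-acid key of a blood clone not
otherwise shared; template counts untouched) to hit a target
intersection of `round(ω · n_tumor_clones)`. Incidental sharing through
the public pool counts toward the target; if it already exceeds ω the
repertoire is left as drawn and the ground truth notes it. Targeting
the realized intersection rather than sampling it makes ω recoverable
to within sampling noise of the tumor clone count (the mean over 50
pairs lands within ±0.01 of ω in practice). Defaults: ω = 0.03 / 0.10 /
0.28 for HIV-negative / ART-experienced / ART-naive.

**Clinical and survival.** Ages are normal (46 ± 13, clipped 18–85);
ART durations respect the 6-month naive/experienced boundary (medians
≈ 0.2 vs ≈ 58 months); HIV-negative patients carry no viral load, CD4
or ART fields. Event times are exponential with rate
`log(2)/12 · exp(η)` where η sums planted log-hazard-ratios (defaults:
ART-naive HR 0.43, HIV-negative HR 0.80 vs the ART-experienced
baseline); progression adds an independent hazard at 0.6× the death
rate so PFS ≤ OS holds by construction; censoring is exponential
(median 48 months) capped at 60 months of follow-up, giving roughly a
third censored.

**Annotation.** Five percent of all observed clonotypes receive
database entries, with species mix InfluenzaA 0.30 / CMV 0.25 /
EBV 0.20 / HIV 0.15 / other 0.10 and a 5% chance of a second species —
enough multi-mapping to exercise the per-species counting rules.

**What the simulator does not emulate.** V(D)J recombination and
generation probabilities, sequencing error, biological sequence
composition, abundance-correlated sharing (public clones are not
preferentially expanded), and the extreme clone-richness of real blood
(symmetric Dirichlet cannot be simultaneously clonal and 10,000-clones
diverse; blood realism favors the clonality contrast). Tests passing on
synthetic cohorts therefore validate the statistical machinery and the
pipeline plumbing, not biological fidelity of any particular dataset.

## Numerical and engineering choices

* Exact-equality contract at `depth = total` is special-cased (see
  above); all other downsampling means are Monte-Carlo with seeded
  streams.
* Expansion-bin boundary closure is right-closed and configurable via
  the bin edges.
* The pipeline stamps every table with a hash of the analysis
  parameters (paths excluded) and is byte-identical across reruns of
  the same configuration; the subcommand path writes the same bytes as
  the single `run` entry point.
* Problem sizes in the test and acceptance runs (e.g. 200 replicates of
  a 12 + 12 two-arm comparison, 50 pairs for overlap recovery, 200
  cohorts of n = 200 for Cox coverage) were chosen to give Monte-Carlo
  error comfortably below the tolerances being asserted.

## Known limitations

* Only the three bulk metrics and the bin profile are implemented — no
  Shannon/Hill diversity, richness estimators, V/J usage, spectratyping
  or sequence-similarity clustering.
* Overlap statistics are presence/absence; no abundance-weighted
  indices.
* AIRR ingest distinguishes stop-codon from out-of-frame rearrangements
  only when the optional `stop_codon` column is present; otherwise
  non-productive rows are read as out-of-frame (the productive subset is
  unaffected).
* Cox models have no proportional-hazards diagnostics, time-varying
  covariates or competing risks.
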