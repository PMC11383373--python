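"""Clone sharing between repertoires: overlap, Venn partition, publicity.

Sharing analyses key clones by CDR3 amino-acid sequence.  Overlap of two
repertoires is the intersection divided by the smaller repertoire;
"public" clones occur in many samples.
"""

from tcrep import CohortConfig, generate_cohort, overlap_matrix, publicity, venn_partition

cohort = generate_cohort(CohortConfig(master_seed=1))
tumors = [r for r in cohort.repertoires if r.tissue.value == "tumor"]
groups = dict(zip(cohort.manifest["sample_id"], cohort.manifest["group"]))

m = overlap_matrix(tumors)
off_diag = m.values[m.values < 1.0]
print(f"tumor overlap matrix: {len(tumors)} samples, "
      f"mean pairwise overlap {off_diag.mean():.4f}")

venn = venn_partition(tumors, groups)
print(f"\n{venn.total} distinct tumor clones by HIV/ART group occupancy:")
for region, count in sorted(venn.region_counts.items(), key=lambda kv: -kv[1]):
    print(f"  {' + '.join(region):>60}: {count:6d} ({100 * count / venn.total:.2f}%)")
# Most clones are private to one group; clones seen in all three groups
# are the shared (often pathogen-directed) public pool.

public = publicity(tumors, min_samples=5, groups=groups)
print(f"\n{len(public)} tumor clones present in >= 5 samples; top 3:")
for rec in public[:3]:
    print(f"  {rec.key}: {rec.sample_count} samples, per group {rec.group_counts}")
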