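"""Build a homology-separated train/test/validation split (85/10/5).

The split is derived from the same clustering machinery as k-fold
partitioning: the data is first divided into n groups, where n is the
smallest integer making both fractions whole numbers of groups, and the
most interconnected groups are merged into the training split.
"""

import homopart as hp

THRESHOLD = 0.5

spec = hp.FamilySpec(
    n_families=40, family_size=5, ancestor_length=150,
    within_mutation_rate=0.05, alphabet="nucleotide", seed=7,
)
records, _ = hp.generate_families(spec)
params = hp.AlignmentParams(alphabet="nucleotide")
sim = hp.build_graph(hp.all_vs_all(records, params), records, THRESHOLD)

split = hp.SplitSpec(test_fraction=0.10, val_fraction=0.05)
print(f"resolved to n={split.n} groups: {split.k_train} train, "
      f"{split.k_test} test, {split.k_val} validation")

clusters = hp.restricted_single_linkage(sim, split.n)
initial = hp.make_tvt_split(sim, clusters, split)
final, trace = hp.separate(sim, initial)

sizes = final.partition_sizes()
total = sum(sizes)
for name, idx in (("train", hp.TRAIN), ("test", hp.TEST), ("validation", hp.VALIDATION)):
    print(f"{name}: {sizes[idx]} sequences ({100 * sizes[idx] / total:.1f}%)")

report = hp.audit_separation(records, final, params, THRESHOLD)
print(f"audit pass: {report.passed}")
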