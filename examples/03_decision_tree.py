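"""Train the information-gain decision tree on per-region frequencies.

Regions are instances, patterns are numeric attributes (proportional
frequencies), splits are binary (<= threshold vs >). With the candidate
attributes restricted to the planted signals the tree reproduces the
two-rule classifier: CCGG* separates VM, AATT* separates NM.
"""

from methylmotif import (
    build_tree,
    count_frequencies,
    default_fixture_spec,
    export_tree,
    generate_fixtures,
    scan_regions,
    training_accuracy,
)
from methylmotif.tree import instances_from_frequencies

regions, _ = generate_fixtures(default_fixture_spec(seed=13))
records = count_frequencies(scan_regions(regions, "both"), regions)
instances = instances_from_frequencies(records, regions)

tree = build_tree(instances, attributes=["AATT*", "CCGG*", "GATCT", "TTTAA"])
print(export_tree(tree, "text"))
print(f"training accuracy: {training_accuracy(tree, instances):.0%} "
      f"on {len(instances)} regions")
# Root = CCGG* (highest information gain: it isolates the VM regions);
# the second split on AATT* separates NM from AM. Thresholds printed are
# observed proportional frequencies, per the C4.5 reporting convention.

full = build_tree(instances)  # all observed patterns as attributes
print(f"\nfull-attribute tree (root {full.attribute}, depth {full.depth()}): "
      f"accuracy {training_accuracy(full, instances):.0%}")
# With thousands of attributes and eight instances many patterns split
# perfectly, so the full tree's root is tie-broken, not unique — a real
# overfitting property of pattern spaces this large at this sample size.
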