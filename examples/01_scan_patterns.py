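"""Scan a single region with the 5 bp wildcard window.

Builds a tiny region, scans both strands, and prints the most frequent
patterns with their proportional frequencies (count / region length).
"""

from methylmotif import GenomicRegion, MethClass, count_frequencies, scan_region

region = GenomicRegion(
    region_id="demo",
    gene="FXN",
    meth_class=MethClass.VM,
    start_bp=101,
    end_bp=160,
    sequence="GATCTACCGGATTTCCGGAACGCGTACCGGTTGATCTAAACCGGCATGCCGGTTAGATCT",
)

occurrences = scan_region(region, strands="both")
print(f"{len(occurrences)} pattern occurrences "
      f"({26} per window x {2 * (region.length_bp - 4)} windows on both strands)")

records = count_frequencies(occurrences, [region])
top = sorted(records, key=lambda r: (-r.count, r.pattern))[:8]
print(f"\ntop patterns in {region.region_id} ({region.length_bp} bp):")
for rec in top:
    print(f"  {rec.pattern}  count={rec.count:3d}  "
          f"proportional_frequency={float(rec.proportional_frequency):.6f}")
# The highest-count patterns are heavily wildcarded (they match many
# windows); the proportional frequency is the per-bp evidence the
# classifier uses.
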