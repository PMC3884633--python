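# methylmotif

Wildcard 5-mer pattern discovery and decision-tree classification of CpG
methylation region classes around trinucleotide-repeat (TNR) loci.

Diseases such as Friedreich's ataxia (*FXN*, GAA repeat), fragile X
syndrome (*FMR1*, CGG repeat) and myotonic dystrophy type I (*DMPK*, CTG
repeat) show aberrant CpG methylation near the expanded repeat. Annotating
each nearby region as **AM** (always methylated), **VM** (variably
methylated — hypermethylated in patients) or **NM** (never methylated),
this package asks whether short sequence motifs in the regions themselves
distinguish the classes. It is aimed at computational epigenetics work on
short (50–600 bp) labelled regions, where general motif finders tuned for
long sequences underperform.

## Method

* **Pattern space.** All 5-symbol motifs over `{A,C,G,T,*}` with ≥ 2 fixed
  bases: `5^5 − 1 − 20 = 3104` patterns. A 5 bp window slides 1 bp at a
  time over each region, on both strands; every full window matches
  exactly 26 patterns (one per subset of 2–5 fixed positions), e.g.
  `GATCT` is counted in `GA**T`, `GA*CT`, …, `GATCT`.
* **Proportional frequency.** Per (pattern, region): pooled both-strand
  count `f` divided by region length `L` in bp, kept as an exact rational.
* **Class sums.** `f/L` summed over the regions of each class identify
  patterns *unique to*, *absent in*, or *enriched in* a class.
* **Decision tree.** Regions are instances, patterns numeric attributes
  (per-region `f/L`); a C4.5-style tree splits at the threshold between
  consecutive values maximizing information gain `H_parent − Σ w_i H_i`
  (bits), reporting the largest observed value ≤ the split point. No
  pruning; gain ratio optional.

Occurrences carry strand, position, exact window sequence and nearest CpG,
and every table exports to TSV; the instance matrix also exports to ARFF
and motifs to MEME minimal format for external cross-checks.

## Worked example

Real region sequences are not redistributable here, so the bundled
generator emulates the study layout: eight regions over the three genes,
`CCGG*` planted in VM regions, `AATT*` planted (denser) in the NM region,
i.i.d. background at GC 0.5. Then:

```bash
methylmotif fixtures --seed 7 --out-dir demo
methylmotif tree --fasta demo/regions.fasta --region-table demo/regions.tsv
```

prints (this exact output, seed 7):

```
***AG <= 0.105000?
|   yes: ***AA <= 0.122727?
|   |   yes: VM (VM:3)
|   |   no:  NM (NM:1)
|   no:  AM (AM:4)
training accuracy: 100.0% on 8 regions
```

Two binary splits on pattern frequencies classify all eight regions —
the two-rule structure the method is built to expose. With 3104
attributes and eight instances many patterns tie as perfect separators,
so the root here is a tie-broken wildcard pattern; restricting the
candidate attributes to the planted signals (see
`examples/03_decision_tree.py`) yields the canonical form — root
`CCGG* <= 0.016000?` isolating VM, then `AATT* <= 0.006667?` separating
NM from AM, thresholds being observed proportional frequencies.

The `examples/` scripts walk each capability (scanning, class
discrimination, the tree, consensus scanning + MEME export) with printed
output explained inline. The full pipeline — occurrence/frequency/summary
TSVs, discrimination reports, instance matrix, ARFF, tree text + JSON,
run log — is one command:

```bash
methylmotif run --config config.yaml --out-dir results_dir
```

with a config as small as `{"fixture": {"seed": 7}}`, or `inputs:` naming
your own FASTA + region TSV (`region_id  gene  meth_class  start_bp
end_bp`).

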