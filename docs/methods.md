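# Methods

## The problem

CpG methylation near trinucleotide-repeat (TNR) expansion loci — such as
the GAA repeat in *FXN* intron 1 (Friedreich's ataxia), the CGG repeat in
the *FMR1* 5′ UTR (fragile X) and the CTG repeat in the *DMPK* 3′ UTR
(myotonic dystrophy type I) — falls into regions that are always
methylated (AM), never methylated (NM), or variably methylated (VM:
aberrantly hypermethylated in patients relative to controls). The question
this package addresses is whether the local DNA sequence itself carries
short motifs that discriminate these classes, i.e. whether sequence
context predisposes a CpG to *de novo* methylation in the disease state.
Methylation status is an **input label** throughout; nothing here calls
methylation from data.

## Wildcard pattern model

The motif space is every 5-symbol string over `{A, C, G, T, *}` with at
least two fixed bases: `5^5 − 1 − 20 = 3104` patterns. The all-wildcard
string and the twenty single-fixed-base strings are excluded because a
single base is not a motif. A concrete 5 bp window matches every pattern
obtained by fixing a subset of 2–5 of its positions, so each window
contributes exactly `C(5,2)+C(5,3)+C(5,4)+C(5,5) = 26` occurrences per
strand — e.g. the window `GATCT` is counted in `GA**T`, `GA*CT`, …, and
`GATCT` itself. Scanning slides the window 1 bp at a time over each full
5 bp window of the region; only full windows are scanned (the bracketed
rendering `[agct]{0,1}` used in report tables is notation for a wildcard,
not a truncation rule at region ends). Both strands are scanned: the minus
strand is the reverse complement, with window starts recorded on that
scanned sequence and a converter back to plus-strand coordinates for the
exports. Windows containing `N` are skipped entirely.

Per region, evidence for pattern *p* is the **proportional frequency**
`f/L`: the pooled both-strand count divided by the region length in bp.
It is held as an exact rational (`fractions.Fraction`) and rendered at
6 decimal places only at output, so aggregation and ranking are free of
floating-point ties. The per-strand occurrence total for an N-free region
is exactly `26·(L−4)`, which yields the conservation identity used in the
tests: summed over all patterns, a class's summed proportional frequencies
equal `26 · Σ_regions s·(L−4)/L` (s = strands scanned).

## Class discrimination

Per-class sums of proportional frequencies support three reports, each
ranked by score descending with lexicographic pattern tie-breaks:

* **unique to a class** — sum > 0 there, exactly 0 in both others;
* **absent in a class** — sum exactly 0 there, scored by the other two
  classes' combined sum. A `deficit` mode drops the zero requirement and
  scores by (others − class), for the "less frequent in X" reading; the
  default is the strict `absent` reading;
* **enriched in a class** — strictly larger sum than each other class.

Uniqueness on sums is equivalent to uniqueness on raw counts (a sum of
non-negative rationals is zero iff every count is zero). Each 5-symbol
string is a distinct pattern; variants differing only in wildcard
placement are never deduplicated. No significance testing is attached to
these rankings — they are descriptive orderings on a handful of regions.

## Decision tree

Instances are regions; attributes are patterns; attribute values are the
**per-region** proportional frequencies (never the class sums); missing
patterns impute to 0. The tree is C4.5-style with binary splits on numeric
attributes: candidate thresholds lie between consecutive distinct sorted
values, the split maximizing information gain (entropy reduction in bits,
`H = −Σ pᵢ log₂ pᵢ`) is chosen, and the *reported* threshold is the
largest observed value not exceeding the midpoint — the C4.5/WEKA
convention, which makes every printed threshold an attainable data value.
Selection uses pure information gain by default; gain ratio is a toggle.
Boundary instances (value == threshold) take the ≤ branch.

Defaults: no pruning, minimum leaf size 1, unlimited depth. With fewer
than ten instances pruning has nothing to work with, and the goal is the
full tree the data induce. Determinism: attribute ties break by score,
then lexicographic pattern text, then lower threshold; leaf-label ties
break to the lexicographically first label. Construction is therefore
independent of instance order.

A property worth stating plainly: with ~3100 attributes and ~8 instances,
many attributes split the training set perfectly and tie at maximal gain,
so the identity of the root under the full attribute set is decided by
tie-breaking, not by the data. Training accuracy of 100% on separable
data is a stable property; the root's name is not. Tests that assert a
specific root therefore either construct instances where a single
attribute separates, or restrict the candidate attribute set — the same
two-rule structure (a CCGG-type split isolating VM, then an AATT-type
split isolating NM) then emerges reproducibly.

## Synthetic data generator

Real region sequences and boundaries for *FXN*/*FMR1*/*DMPK* are not
bundled (they are published only as an annotated figure), so the
generator emulates the study layout: eight regions across the three
genes — FXN VM / AM_1 / AM_2, FMR1 VM / AM, DMPK VM / AM / NM — with
lengths 200–400 bp (within the 50–600 bp range typical of such regions),
i.i.d. background bases at GC 0.5, `CCGG*` planted in the VM regions at
1 copy per 20 bp and `AATT*` in the NM region at 1 copy per 15 bp.
Those densities put the planted signal roughly an order of magnitude
above the i.i.d. background expectation for a 4-fixed-base pattern
(~2/256 per bp on two strands), which is what "a motif marks this region
class" means under this model. Planted copies never overlap each other;
requests that cannot fit raise an error. Background windows may still
collide with a planted pattern — collisions are left in place and
recorded ground truth gives the planted positions, so observed counts are
lower-bounded by, not equal to, the planted copy number.

What the generator does **not** emulate: the TNR tract itself, CpG-island
base composition and CpG clustering, repeat-induced secondary structure,
and any dependence between neighbouring bases. Passing tests on this
fixture show the machinery is correct and that planted signal of the
stated strength is recovered; they say nothing about whether real AM/VM/NM
regions carry such signal.

## Numerical and I/O choices

* Coordinates are 1-based inclusive in gene-local numbering; BED-style
  0-based half-open input would be converted on read.
* Sequences are uppercased on read; lowercase pattern renderings in
  report tables are presentation only.
* Nearest-CpG annotation measures distance from the window start in
  plus-strand coordinates (minus-strand starts are converted); ties break
  to the lower CpG position.
* All TSVs are written through pandas; FASTA through Biopython; the tree
  serializes to indented text (thresholds at 6 d.p.) and to lossless JSON
  (thresholds as exact rational strings); the ARFF export allows
  cross-checking the instance matrix in external ML tools; the MEME
  minimal motif export writes one-hot rows for fixed positions and the
  background distribution for wildcards. MEME, TOMTOM and WEKA are never
  invoked.
* The pipeline log is timestamp-free and stores paths relative to the
  bundle root, so identical configs give byte-identical bundles.

## Problem sizes

The bundled analyses run on the eight-region synthetic layout (~2.2 kb of
sequence, ~115 k occurrence records on both strands) and on randomized
regions of 20–200 bp for oracle comparisons; both complete in seconds.

## Known limitations

* The pattern length (5) and the ≥2-fixed-bases rule are constants of the
  method, validated but not configurable.
* Discrimination reports are descriptive; with three VM, four AM and one
  NM region any ranking is sensitive to single regions.
* The tree is fit and evaluated on the training regions only — there is
  deliberately no cross-validation machinery at n = 8.
* Reproducing the published counts and sums for the real *FXN*/*FMR1*/
  *DMPK* regions requires obtaining those sequences and boundaries
  externally; the schema (FASTA + region TSV) is ready for them.
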