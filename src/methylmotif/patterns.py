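"""Wildcard 5-mer pattern engine: enumeration, scanning, and frequency tables.

The feature space is every 5-symbol string over ``{A, C, G, T, *}`` with at
least two fixed (non-``*``) bases — 3104 patterns in total
(``5**5 - 1 - 20``: the all-wildcard string and the twenty one-fixed-base
strings are excluded, since a single fixed base is not a motif).  A concrete
5 bp window matches every pattern obtained by keeping any subset of 2-5 of
its positions fixed and wildcarding the rest, so each window contributes
exactly ``C(5,2)+C(5,3)+C(5,4)+C(5,5) = 26`` pattern occurrences per strand.

A region is scanned with a 5 bp window sliding 1 bp at a time, on the plus
strand and on the reverse complement; windows containing ``N`` are skipped.
Per-region evidence for a pattern is its *proportional frequency*: the
pooled (both-strand) occurrence count divided by the region length in bp,
kept as an exact rational and rendered at 6 decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .regions import CpGSite, GenomicRegion, reverse_complement

__all__ = [
    "PATTERN_LENGTH",
    "MIN_FIXED",
    "PATTERNS_PER_WINDOW",
    "WildcardPattern",
    "PatternOccurrence",
    "FrequencyRecord",
    "enumerate_patterns",
    "window_patterns",
    "scan_region",
    "scan_regions",
    "annotate_nearest_cpg",
    "count_frequencies",
    "occurrences_to_frame",
    "frequencies_to_frame",
    "minus_start_to_plus",
]

PATTERN_LENGTH = 5
MIN_FIXED = 2
WILDCARD = "*"
#: number of >=2-fixed patterns matching any concrete 5-mer: C(5,2..5) summed
PATTERNS_PER_WINDOW = 26

Strand = Literal["+", "-"]
StrandChoice = Literal["plus", "minus", "both"]


@dataclass(frozen=True, order=True)
class WildcardPattern:
    """A 5-symbol wildcard motif, e.g. ``GA**T``."""

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != PATTERN_LENGTH:
            raise ValueError(f"pattern must have {PATTERN_LENGTH} symbols: {self.symbols!r}")
        bad = set(self.symbols) - set("ACGT" + WILDCARD)
        if bad:
            raise ValueError(f"invalid pattern symbols {sorted(bad)} in {self.symbols!r}")
        if self.fixed_count < MIN_FIXED:
            raise ValueError(
                f"pattern {self.symbols!r} has {self.fixed_count} fixed bases; "
                f"at least {MIN_FIXED} required"
            )

    @property
    def fixed_count(self) -> int:
        return sum(1 for s in self.symbols if s != WILDCARD)

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        """0-based positions of the fixed bases."""
        return tuple(i for i, s in enumerate(self.symbols) if s != WILDCARD)

    def matches(self, window: str) -> bool:
        """Character-by-character match of a concrete 5-mer."""
        if len(window) != PATTERN_LENGTH:
            return False
        return all(s == WILDCARD or s == c for s, c in zip(self.symbols, window))

    def __str__(self) -> str:
        return self.symbols


@dataclass(frozen=True)
class PatternOccurrence:
    """One window match: which pattern, where, on which strand.

    ``start`` is the 1-based offset of the window's first base *within the
    scanned strand's sequence* (for the minus strand, within the reverse
    complement).  ``nearest_cpg_position`` is filled by
    :func:`annotate_nearest_cpg` and is always in plus-strand region
    coordinates.
    """

    pattern: str
    region_id: str
    strand: Strand
    start: int
    window_sequence: str
    nearest_cpg_position: Optional[int] = None


@dataclass(frozen=True)
class FrequencyRecord:
    """Pooled both-strand count of a pattern in a region, with its
    proportional frequency ``count / region_length_bp`` as an exact rational."""

    pattern: str
    region_id: str
    count: int
    region_length_bp: int

    @property
    def proportional_frequency(self) -> Fraction:
        return Fraction(self.count, self.region_length_bp)


# 26 position subsets of size 2..5, in a deterministic order
_SUBSETS: tuple[tuple[int, ...], ...] = tuple(
    subset
    for k in range(MIN_FIXED, PATTERN_LENGTH + 1)
    for subset in combinations(range(PATTERN_LENGTH), k)
)


def enumerate_patterns() -> list[WildcardPattern]:
    """All 3104 wildcard patterns, in lexicographic order of their text form.

    Lexicographic order uses ASCII, where ``*`` sorts before the bases, so
    e.g. ``**AAA`` precedes ``AAAAA``.
    """
    alphabet = sorted("ACGT" + WILDCARD)
    patterns = []

    def extend(prefix: str) -> None:
        if len(prefix) == PATTERN_LENGTH:
            if sum(1 for s in prefix if s != WILDCARD) >= MIN_FIXED:
                patterns.append(WildcardPattern(prefix))
            return
        for symbol in alphabet:
            extend(prefix + symbol)

    extend("")
    return patterns


def window_patterns(window: str) -> set[WildcardPattern]:
    """The 26 patterns a concrete 5-mer is counted in.

    E.g. ``GATCT`` is counted in ``GA**T``, ``GA*CT``, ... and in ``GATCT``
    itself.  A window containing ``N`` yields the empty set.
    """
    window = window.upper()
    if len(window) != PATTERN_LENGTH:
        raise ValueError(f"window must be {PATTERN_LENGTH} bp, got {window!r}")
    if "N" in window:
        return set()
    result = set()
    for subset in _SUBSETS:
        symbols = "".join(
            window[i] if i in subset else WILDCARD for i in range(PATTERN_LENGTH)
        )
        result.add(WildcardPattern(symbols))
    return result


def _window_pattern_strings(window: str) -> list[str]:
    # hot path: plain strings, no dataclass construction
    return [
        "".join(window[i] if i in subset else WILDCARD for i in range(PATTERN_LENGTH))
        for subset in _SUBSETS
    ]


def scan_region(
    region: GenomicRegion, strands: StrandChoice = "both"
) -> list[PatternOccurrence]:
    """Slide a 5 bp window along the region and record every pattern match.

    Each full N-free window emits 26 occurrences per scanned strand.
    Minus-strand scanning operates on the reverse complement, with ``start``
    recorded on that scanned sequence.  Regions shorter than 5 bp yield no
    occurrences.
    """
    strand_seqs: list[tuple[Strand, str]] = []
    if strands in ("plus", "both"):
        strand_seqs.append(("+", region.sequence))
    if strands in ("minus", "both"):
        strand_seqs.append(("-", reverse_complement(region.sequence)))

    occurrences: list[PatternOccurrence] = []
    for strand, seq in strand_seqs:
        for start0 in range(len(seq) - PATTERN_LENGTH + 1):
            window = seq[start0 : start0 + PATTERN_LENGTH]
            if "N" in window:
                continue
            for symbols in _window_pattern_strings(window):
                occurrences.append(
                    PatternOccurrence(
                        pattern=symbols,
                        region_id=region.region_id,
                        strand=strand,
                        start=start0 + 1,
                        window_sequence=window,
                    )
                )
    return occurrences


def scan_regions(
    regions: Sequence[GenomicRegion], strands: StrandChoice = "both"
) -> list[PatternOccurrence]:
    """Scan several regions; occurrences are concatenated in region order."""
    out: list[PatternOccurrence] = []
    for region in regions:
        out.extend(scan_region(region, strands))
    return out


def minus_start_to_plus(start: int, region_length: int) -> int:
    """Convert a minus-strand window start (1-based, on the reverse
    complement) to the window's start on the plus strand."""
    return region_length - (start + PATTERN_LENGTH - 1) + 1


def annotate_nearest_cpg(
    occurrences: Iterable[PatternOccurrence],
    cpg_sites: Sequence[CpGSite],
    region_length: Optional[int] = None,
) -> list[PatternOccurrence]:
    """Fill ``nearest_cpg_position`` with the CpG closest to the window start.

    Distances are measured on plus-strand region coordinates (minus-strand
    starts are converted, which requires ``region_length``).  Ties break to
    the lower CpG position.  With no CpG sites the field stays ``None``.
    """
    positions = sorted(site.position for site in cpg_sites)
    annotated = []
    for occ in occurrences:
        if not positions:
            annotated.append(occ)
            continue
        if occ.strand == "-":
            if region_length is None:
                raise ValueError("region_length required to annotate minus-strand occurrences")
            ref = minus_start_to_plus(occ.start, region_length)
        else:
            ref = occ.start
        nearest = min(positions, key=lambda p: (abs(p - ref), p))
        annotated.append(replace(occ, nearest_cpg_position=nearest))
    return annotated


def count_frequencies(
    occurrences: Iterable[PatternOccurrence],
    regions: Sequence[GenomicRegion],
    include_zero: bool = False,
) -> list[FrequencyRecord]:
    """Pool plus- and minus-strand occurrences into per-(pattern, region)
    counts and proportional frequencies.

    By default only patterns with ``count > 0`` are materialized; with
    ``include_zero`` a record is emitted for every one of the 3104 patterns
    in every region.  Records are ordered by region (input order), then
    pattern.
    """
    lengths = {r.region_id: r.length_bp for r in regions}
    counts: dict[tuple[str, str], int] = {}
    for occ in occurrences:
        if occ.region_id not in lengths:
            raise KeyError(f"occurrence references unknown region {occ.region_id!r}")
        key = (occ.region_id, occ.pattern)
        counts[key] = counts.get(key, 0) + 1

    records = []
    if include_zero:
        all_patterns = [p.symbols for p in enumerate_patterns()]
        for region in regions:
            for symbols in all_patterns:
                records.append(
                    FrequencyRecord(
                        pattern=symbols,
                        region_id=region.region_id,
                        count=counts.get((region.region_id, symbols), 0),
                        region_length_bp=lengths[region.region_id],
                    )
                )
    else:
        region_order = {r.region_id: i for i, r in enumerate(regions)}
        for region_id, symbols in sorted(
            counts, key=lambda key: (region_order[key[0]], key[1])
        ):
            records.append(
                FrequencyRecord(
                    pattern=symbols,
                    region_id=region_id,
                    count=counts[(region_id, symbols)],
                    region_length_bp=lengths[region_id],
                )
            )
    return records


def occurrences_to_frame(
    occurrences: Iterable[PatternOccurrence],
    regions: Sequence[GenomicRegion],
) -> pd.DataFrame:
    """Occurrence table mirroring the per-match audit export: pattern,
    region, gene, class, strand, start, exact window, nearest CpG."""
    meta = {r.region_id: r for r in regions}
    rows = []
    for occ in occurrences:
        region = meta[occ.region_id]
        rows.append(
            {
                "pattern": occ.pattern,
                "region_id": occ.region_id,
                "gene": region.gene,
                "meth_class": region.meth_class.value,
                "strand": occ.strand,
                "start": occ.start,
                "window_sequence": occ.window_sequence,
                "nearest_cpg_position": occ.nearest_cpg_position,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pattern",
            "region_id",
            "gene",
            "meth_class",
            "strand",
            "start",
            "window_sequence",
            "nearest_cpg_position",
        ],
    )


def frequencies_to_frame(records: Iterable[FrequencyRecord]) -> pd.DataFrame:
    """Frequency table with proportional frequencies rendered at 6 d.p."""
    rows = [
        {
            "pattern": rec.pattern,
            "region_id": rec.region_id,
            "count": rec.count,
            "region_length_bp": rec.region_length_bp,
            "proportional_frequency": f"{float(rec.proportional_frequency):.6f}",
        }
        for rec in records
    ]
    return pd.DataFrame(
        rows,
        columns=["pattern", "region_id", "count", "region_length_bp", "proportional_frequency"],
    )
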