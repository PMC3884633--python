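"""Pattern enumeration, window matching, scanning and frequency tables."""

from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylmotif import (
    PATTERNS_PER_WINDOW,
    CpGSite,
    WildcardPattern,
    annotate_nearest_cpg,
    count_frequencies,
    enumerate_patterns,
    scan_region,
    window_patterns,
)
from methylmotif.patterns import frequencies_to_frame, minus_start_to_plus

from conftest import make_region, random_sequence

windows = st.text(alphabet="ACGT", min_size=5, max_size=5)

ALL_PATTERNS = enumerate_patterns()


def test_pattern_space_matches_bruteforce_enumeration():
    # independent oracle: all 5^5 strings, drop <2-fixed ones
    oracle = {
        "".join(s)
        for s in product("ACGT*", repeat=5)
        if sum(1 for c in s if c != "*") >= 2
    }
    patterns = enumerate_patterns()
    assert {p.symbols for p in patterns} == oracle
    assert len(patterns) == 3104 == 5**5 - 1 - 20
    assert all(2 <= p.fixed_count <= 5 for p in patterns)
    # deterministic lexicographic iteration order
    symbols = [p.symbols for p in patterns]
    assert symbols == sorted(symbols)


@pytest.mark.parametrize("bad", ["A****", "*****", "GATC", "GATCTT", "GAUCT"])
def test_invalid_patterns_rejected(bad):
    with pytest.raises(ValueError):
        WildcardPattern(bad)


def test_window_patterns_gatct():
    result = {p.symbols for p in window_patterns("GATCT")}
    assert "GA**T" in result
    assert "GA*CT" in result
    assert "GATCT" in result  # the zero-wildcard subset
    assert len(result) == PATTERNS_PER_WINDOW == 26


@given(window=windows)
@settings(max_examples=100, deadline=None)
def test_window_patterns_match_subset_oracle(window):
    # oracle: every >=2-fixed pattern that matches character by character
    oracle = {p.symbols for p in ALL_PATTERNS if p.matches(window)}
    result = {p.symbols for p in window_patterns(window)}
    assert result == oracle
    assert len(result) == 26


def test_window_with_n_is_skipped():
    assert window_patterns("GANCT") == set()


@pytest.mark.parametrize(
    "seq, strands, expected",
    [
        ("GATCTA", "plus", 2 * 26),
        ("GATCT", "both", 2 * 26),
        ("GATC", "both", 0),
        ("GANCTA", "plus", 0),  # both windows contain the N
    ],
)
def test_scan_region_occurrence_totals(seq, strands, expected):
    assert len(scan_region(make_region(seq), strands)) == expected


def test_per_strand_totals(rng):
    for length in (20, 57, 123):
        region = make_region(random_sequence(rng, length))
        assert len(scan_region(region, "plus")) == 26 * (length - 4)
        assert len(scan_region(region, "both")) == 2 * 26 * (length - 4)


def test_scan_counts_match_naive_char_oracle(rng):
    """Pooled counts equal testing every pattern against every window
    character by character, on both strands."""
    from methylmotif import reverse_complement

    patterns = ALL_PATTERNS
    for _ in range(3):
        seq = random_sequence(rng, 60)
        region = make_region(seq)
        records = count_frequencies(scan_region(region, "both"), [region])
        counted = {rec.pattern: rec.count for rec in records}
        rc = reverse_complement(seq)
        for pattern in patterns:
            naive = sum(
                pattern.matches(s[i : i + 5])
                for s in (seq, rc)
                for i in range(len(s) - 4)
            )
            assert counted.get(pattern.symbols, 0) == naive


def test_scan_is_deterministic(rng):
    region = make_region(random_sequence(rng, 80))
    assert scan_region(region, "both") == scan_region(region, "both")


def test_annotate_nearest_cpg_rules():
    region = make_region("A" * 30)
    occ = scan_region(region, "plus")
    ten = [o for o in occ if o.start == 10][0]

    sites = [CpGSite("R1", 2), CpGSite("R1", 12)]
    (annotated,) = annotate_nearest_cpg([ten], sites, region.length_bp)
    assert annotated.nearest_cpg_position == 12  # |10-12| < |10-2|

    tie = [CpGSite("R1", 8), CpGSite("R1", 12)]
    (annotated,) = annotate_nearest_cpg([ten], tie, region.length_bp)
    assert annotated.nearest_cpg_position == 8  # equidistant -> lower wins

    (annotated,) = annotate_nearest_cpg([ten], [], region.length_bp)
    assert annotated.nearest_cpg_position is None


def test_annotate_nearest_cpg_minus_strand_uses_plus_coordinates():
    region = make_region("CGAAAAAAAAAAAAAAAAAA")  # CpG at plus position 1
    minus = [o for o in scan_region(region, "minus") if o.start == 1]
    annotated = annotate_nearest_cpg(minus, [CpGSite("R1", 1)], region.length_bp)
    assert all(o.nearest_cpg_position == 1 for o in annotated)
    # minus-strand start 1 covers the last 5 plus-strand bases
    assert minus_start_to_plus(1, region.length_bp) == 16


def test_count_frequencies_arithmetic():
    region = make_region("GATCT" + "A" * 65)  # length 70
    records = count_frequencies(scan_region(region, "plus"), [region])
    by_pattern = {r.pattern: r for r in records}
    rec = by_pattern["GA*CT"]
    assert rec.count == 1
    assert rec.proportional_frequency == Fraction(1, 70)
    frame = frequencies_to_frame([rec])
    assert frame.loc[0, "proportional_frequency"] == "0.014286"
    # unknown region -> fatal
    with pytest.raises(KeyError):
        count_frequencies(scan_region(region, "plus"), [])


def test_proportional_frequency_bound(rng):
    """pf <= 2*(L-4)/L when both strands are scanned."""
    for length in (20, 61, 150):
        region = make_region(random_sequence(rng, length, gc=0.3))
        records = count_frequencies(scan_region(region, "both"), [region])
        bound = Fraction(2 * (length - 4), length)
        assert all(r.proportional_frequency <= bound for r in records)
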