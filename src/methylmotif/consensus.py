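"""IUPAC consensus scanning, e.g. surveying regions for CTCF binding sites.

The consensus string itself is user-supplied; any IUPAC ambiguity code is
accepted (``R`` = A/G, ``N`` = any base, ...).  Matching slides a window of
the consensus length along the plus strand and, when requested, the reverse
complement, and keeps windows satisfying every position's code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .regions import GenomicRegion, reverse_complement

__all__ = ["ConsensusMatch", "consensus_scan", "matches_to_frame"]

# e.g. "R" -> {"A", "G"}; "N" -> {A,C,G,T}; biopython's extra "X" alias excluded
_IUPAC_SETS = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code in set("ACGTRYSWKMBDHVN")
}


@dataclass(frozen=True)
class ConsensusMatch:
    """One window satisfying the consensus; ``start`` is 1-based on the
    scanned strand's sequence."""

    region_id: str
    strand: Literal["+", "-"]
    start: int
    matched_sequence: str


def consensus_scan(
    region: GenomicRegion,
    consensus: str,
    strands: Literal["plus", "minus", "both"] = "both",
) -> list[ConsensusMatch]:
    """Every full window of ``len(consensus)`` bp matching the IUPAC
    consensus at all positions, on the requested strands."""
    consensus = consensus.upper()
    sets = []
    for i, code in enumerate(consensus):
        if code not in _IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i + 1}")
        sets.append(_IUPAC_SETS[code])
    k = len(consensus)

    strand_seqs: list[tuple[Literal["+", "-"], str]] = []
    if strands in ("plus", "both"):
        strand_seqs.append(("+", region.sequence))
    if strands in ("minus", "both"):
        strand_seqs.append(("-", reverse_complement(region.sequence)))

    matches = []
    for strand, seq in strand_seqs:
        for start0 in range(len(seq) - k + 1):
            window = seq[start0 : start0 + k]
            if all(base in allowed for base, allowed in zip(window, sets)):
                matches.append(
                    ConsensusMatch(
                        region_id=region.region_id,
                        strand=strand,
                        start=start0 + 1,
                        matched_sequence=window,
                    )
                )
    return matches


def matches_to_frame(matches: Sequence[ConsensusMatch], consensus: str) -> pd.DataFrame:
    rows = [
        {
            "consensus": consensus,
            "region_id": m.region_id,
            "strand": m.strand,
            "start": m.start,
            "matched_sequence": m.matched_sequence,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows, columns=["consensus", "region_id", "strand", "start", "matched_sequence"]
    )
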