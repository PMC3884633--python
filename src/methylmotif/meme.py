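"""MEME minimal motif format export (and a round-trip parser).

Each wildcard pattern becomes a letter-probability matrix: fixed positions
are one-hot on the fixed base, wildcard positions carry the background
distribution.  The export enables comparison workflows in the MEME suite;
this package never runs MEME itself.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .patterns import WildcardPattern

__all__ = ["export_meme_minimal", "parse_meme_minimal", "UNIFORM_BACKGROUND"]

ALPHABET = "ACGT"
UNIFORM_BACKGROUND: dict[str, float] = {b: 0.25 for b in ALPHABET}


def export_meme_minimal(
    patterns_with_counts: Sequence[tuple[WildcardPattern, int]],
    background: Mapping[str, float] = UNIFORM_BACKGROUND,
) -> str:
    """Render patterns as a MEME minimal motif file (version 4).

    ``patterns_with_counts`` pairs each pattern with its site count
    (``nsites``); counts must be positive.
    """
    if not patterns_with_counts:
        raise ValueError("need at least one pattern to export")
    total = sum(background.get(b, 0.0) for b in ALPHABET)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"background frequencies sum to {total}, expected 1")

    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{b} {background[b]:.6f}" for b in ALPHABET))
    lines.append("")
    for pattern, count in patterns_with_counts:
        if count <= 0:
            raise ValueError(f"pattern {pattern.symbols!r} has non-positive count {count}")
        lines.append(f"MOTIF {pattern.symbols}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(pattern.symbols)} "
            f"nsites= {count} E= 0"
        )
        for symbol in pattern.symbols:
            if symbol == "*":
                row = [background[b] for b in ALPHABET]
            else:
                row = [1.0 if b == symbol else 0.0 for b in ALPHABET]
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    return "\n".join(lines)


def parse_meme_minimal(text: str) -> list[tuple[str, int, list[list[float]]]]:
    """Parse a minimal motif file back into (motif name, nsites, matrix)
    triples; used for round-trip validation."""
    motifs = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            header = lines[i].strip()
            if not header.startswith("letter-probability matrix:"):
                raise ValueError(f"motif {name!r}: missing letter-probability header")
            fields = dict(
                zip(header.split()[2::2], header.split()[3::2])
            )  # alength=, w=, nsites=, E=
            width = int(fields["w="])
            nsites = int(fields["nsites="])
            matrix = []
            for j in range(width):
                i += 1
                row = [float(x) for x in lines[i].split()]
                if len(row) != 4:
                    raise ValueError(f"motif {name!r}: row {j + 1} has {len(row)} columns")
                matrix.append(row)
            motifs.append((name, nsites, matrix))
        i += 1
    return motifs
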