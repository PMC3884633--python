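"""Labelled DNA regions: reading, validation, strand and CpG utilities.

A *region* is a short DNA segment near a trinucleotide-repeat locus,
annotated with its gene of origin and a methylation class:

* ``AM`` — always methylated (in both patients and controls),
* ``VM`` — variably methylated (aberrantly hypermethylated in patients),
* ``NM`` — never methylated.

Regions are the unit of pattern counting and the instances of the
downstream classifier.  Coordinates are 1-based inclusive in a gene-local
numbering; sequences are uppercase over ``{A, C, G, T, N}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MethClass",
    "GenomicRegion",
    "CpGSite",
    "RegionValidationError",
    "read_regions",
    "read_region_table",
    "find_cpg_sites",
    "reverse_complement",
]

DNA_ALPHABET = frozenset("ACGTN")

REGION_TABLE_COLUMNS = ["region_id", "gene", "meth_class", "start_bp", "end_bp"]


class MethClass(str, Enum):
    """Methylation class of a region."""

    AM = "AM"
    VM = "VM"
    NM = "NM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RegionValidationError(ValueError):
    """Raised when a region or region set violates an invariant."""


@dataclass(frozen=True)
class GenomicRegion:
    """A labelled DNA segment.

    Parameters
    ----------
    region_id : str
        Short unique identifier (FASTA record id).
    gene : str
        Gene of origin, e.g. ``"FXN"``, ``"FMR1"``, ``"DMPK"``.
    meth_class : MethClass
        Methylation class label (AM / VM / NM).
    start_bp, end_bp : int
        1-based inclusive coordinates in the gene-local numbering.
    sequence : str
        Uppercase DNA sequence; its length must equal
        ``end_bp - start_bp + 1``.
    """

    region_id: str
    gene: str
    meth_class: MethClass
    start_bp: int
    end_bp: int
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "meth_class", MethClass(self.meth_class))
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise RegionValidationError(
                f"region {self.region_id!r}: non-DNA characters {sorted(bad)}"
            )
        expected = self.end_bp - self.start_bp + 1
        if expected < 1:
            raise RegionValidationError(
                f"region {self.region_id!r}: empty coordinate interval "
                f"[{self.start_bp}, {self.end_bp}]"
            )
        if len(self.sequence) != expected:
            raise RegionValidationError(
                f"region {self.region_id!r}: sequence length {len(self.sequence)} "
                f"does not match coordinates [{self.start_bp}, {self.end_bp}] "
                f"(expected {expected} bp)"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide within a region.

    ``position`` is the 1-based offset of the C within the region sequence.
    """

    region_id: str
    position: int


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Raises ``RegionValidationError`` on non-DNA characters.
    """
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise RegionValidationError(f"non-DNA characters {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def find_cpg_sites(region: GenomicRegion) -> list[CpGSite]:
    """Tag every CG dinucleotide in the region, positions ascending."""
    seq = region.sequence
    sites = []
    pos = seq.find("CG")
    while pos != -1:
        sites.append(CpGSite(region_id=region.region_id, position=pos + 1))
        pos = seq.find("CG", pos + 1)
    return sites


def read_region_table(source: Union[str, Path]) -> pd.DataFrame:
    """Read the region-annotation TSV.

    Columns: ``region_id``, ``gene``, ``meth_class``, ``start_bp``, ``end_bp``.
    """
    table = pd.read_csv(source, sep="\t", dtype={"region_id": str, "gene": str})
    missing = [c for c in REGION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise RegionValidationError(f"region table missing columns: {missing}")
    return table


def read_regions(
    fasta_source: Union[str, Path],
    region_table_source: Union[str, Path, pd.DataFrame],
) -> list[GenomicRegion]:
    """Read and validate labelled regions from FASTA plus an annotation table.

    FASTA record ids must match ``region_id`` values; ordering follows the
    table.  Fatal errors: missing FASTA record, coordinate/sequence length
    mismatch, unknown class token, overlapping same-gene regions.
    """
    if isinstance(region_table_source, pd.DataFrame):
        table = region_table_source
        missing = [c for c in REGION_TABLE_COLUMNS if c not in table.columns]
        if missing:
            raise RegionValidationError(f"region table missing columns: {missing}")
    else:
        table = read_region_table(region_table_source)

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_source), "fasta")}

    regions = []
    for row in table.itertuples(index=False):
        region_id = str(row.region_id)
        if region_id not in records:
            raise RegionValidationError(
                f"region {region_id!r}: no matching FASTA record"
            )
        try:
            meth_class = MethClass(str(row.meth_class))
        except ValueError as exc:
            raise RegionValidationError(
                f"region {region_id!r}: unknown class token {row.meth_class!r} "
                f"(expected one of AM, VM, NM)"
            ) from exc
        regions.append(
            GenomicRegion(
                region_id=region_id,
                gene=str(row.gene),
                meth_class=meth_class,
                start_bp=int(row.start_bp),
                end_bp=int(row.end_bp),
                sequence=records[region_id],
            )
        )
    validate_region_set(regions)
    return regions


def validate_region_set(regions: Sequence[GenomicRegion]) -> None:
    """Reject duplicate ids and overlapping same-gene coordinate intervals."""
    seen: set[str] = set()
    for region in regions:
        if region.region_id in seen:
            raise RegionValidationError(f"duplicate region_id {region.region_id!r}")
        seen.add(region.region_id)
    by_gene: dict[str, list[GenomicRegion]] = {}
    for region in regions:
        by_gene.setdefault(region.gene, []).append(region)
    for gene, group in by_gene.items():
        group = sorted(group, key=lambda r: r.start_bp)
        for a, b in zip(group, group[1:]):
            if b.start_bp <= a.end_bp:
                raise RegionValidationError(
                    f"gene {gene!r}: regions {a.region_id!r} and {b.region_id!r} "
                    f"overlap ([{a.start_bp},{a.end_bp}] vs [{b.start_bp},{b.end_bp}])"
                )


def write_regions_fasta(regions: Iterable[GenomicRegion], path: Union[str, Path]) -> None:
    """Write one FASTA record per region (id == region_id)."""
    with open(path, "w") as handle:
        for region in regions:
            handle.write(f">{region.region_id}\n")
            seq = region.sequence
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def regions_to_table(regions: Iterable[GenomicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "gene": r.gene,
                "meth_class": r.meth_class.value,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
            }
            for r in regions
        ],
        columns=REGION_TABLE_COLUMNS,
    )
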