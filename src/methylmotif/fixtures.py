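"""Seeded synthetic region fixtures with planted wildcard patterns.

Real inputs for this analysis are the methylation-annotated regions around
the FXN, FMR1 and DMPK trinucleotide repeats, which are not bundled here.
The generator emulates their layout: a handful of 50-600 bp regions per
gene, each labelled AM/VM/NM, with i.i.d. background bases at a chosen GC
fraction and wildcard patterns planted at controlled densities.  The
default spec mirrors the study design — eight regions across three genes,
CCGG* planted in the variably methylated regions and AATT* at a higher
per-bp rate in the never methylated region — so the planted signal is the
one the downstream tree should discover.

Everything is reproducible from the seed; planted occurrences are recorded
as ground truth.  Background windows may also happen to match a planted
pattern; such collisions are expected and left in place, so observed counts
are lower-bounded (not equal) to the planted copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .patterns import PATTERN_LENGTH, WildcardPattern
from .regions import GenomicRegion, MethClass, regions_to_table, write_regions_fasta

__all__ = [
    "PlantSpec",
    "RegionSpec",
    "FixtureSpec",
    "generate_fixtures",
    "write_fixtures",
    "default_fixture_spec",
    "load_fixture_spec",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """A pattern to embed: either an absolute copy number or a per-bp rate
    (converted to ``round(rate * length_bp)`` copies)."""

    pattern: str
    copies: Optional[int] = None
    rate: Optional[float] = None

    def __post_init__(self) -> None:
        WildcardPattern(self.pattern)  # validate
        if (self.copies is None) == (self.rate is None):
            raise ValueError(f"plant {self.pattern!r}: give exactly one of copies/rate")

    def resolved_copies(self, length_bp: int) -> int:
        if self.copies is not None:
            return self.copies
        return int(round(self.rate * length_bp))


@dataclass(frozen=True)
class RegionSpec:
    region_id: str
    gene: str
    meth_class: str
    length_bp: int
    gc_fraction: float = 0.5
    planted: tuple[PlantSpec, ...] = ()

    def __post_init__(self) -> None:
        MethClass(self.meth_class)
        if self.length_bp < PATTERN_LENGTH:
            raise ValueError(
                f"region {self.region_id!r}: length {self.length_bp} < {PATTERN_LENGTH}"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"region {self.region_id!r}: gc_fraction out of [0,1]")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    regions: tuple[RegionSpec, ...]


class InfeasiblePlantingError(ValueError):
    """Requested planted copies cannot fit without overlap."""


def _sample_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(BASES, size=length, p=probs)


def _realize(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        s if s != "*" else str(rng.choice(BASES)) for s in pattern
    )


def generate_fixtures(
    spec: FixtureSpec,
) -> tuple[list[GenomicRegion], pd.DataFrame]:
    """Generate regions and a ground-truth table of planted occurrences.

    Plantings within a region never overlap each other; infeasible requests
    (too many copies for the length) raise :class:`InfeasiblePlantingError`.
    Gene-local coordinates are assigned sequentially per gene with a 50 bp
    gap, so same-gene regions never overlap.
    """
    rng = np.random.default_rng(spec.seed)
    regions: list[GenomicRegion] = []
    truth_rows = []
    next_start: dict[str, int] = {}

    for rspec in spec.regions:
        total_copies = sum(p.resolved_copies(rspec.length_bp) for p in rspec.planted)
        if total_copies * PATTERN_LENGTH > rspec.length_bp:
            raise InfeasiblePlantingError(
                f"region {rspec.region_id!r}: {total_copies} planted copies x "
                f"{PATTERN_LENGTH} bp exceed length {rspec.length_bp}"
            )
        seq = _sample_background(rng, rspec.length_bp, rspec.gc_fraction)

        # choose non-overlapping plant positions, one draw at a time
        available = set(range(rspec.length_bp - PATTERN_LENGTH + 1))
        for plant in rspec.planted:
            for _ in range(plant.resolved_copies(rspec.length_bp)):
                if not available:
                    raise InfeasiblePlantingError(
                        f"region {rspec.region_id!r}: no non-overlapping slot left "
                        f"for pattern {plant.pattern!r}"
                    )
                start0 = int(rng.choice(sorted(available)))
                realized = _realize(rng, plant.pattern)
                seq[start0 : start0 + PATTERN_LENGTH] = list(realized)
                for occupied in range(
                    start0 - PATTERN_LENGTH + 1, start0 + PATTERN_LENGTH
                ):
                    available.discard(occupied)
                truth_rows.append(
                    {
                        "region_id": rspec.region_id,
                        "pattern": plant.pattern,
                        "start": start0 + 1,
                        "realized_sequence": realized,
                    }
                )

        start_bp = next_start.get(rspec.gene, 101)
        end_bp = start_bp + rspec.length_bp - 1
        next_start[rspec.gene] = end_bp + 51
        regions.append(
            GenomicRegion(
                region_id=rspec.region_id,
                gene=rspec.gene,
                meth_class=MethClass(rspec.meth_class),
                start_bp=start_bp,
                end_bp=end_bp,
                sequence="".join(seq),
            )
        )

    truth = pd.DataFrame(
        truth_rows, columns=["region_id", "pattern", "start", "realized_sequence"]
    )
    return regions, truth


def write_fixtures(
    spec: FixtureSpec, out_dir: Union[str, Path]
) -> tuple[Path, Path, Path]:
    """Write FASTA, region-annotation TSV and ground-truth TSV; returns the
    three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    regions, truth = generate_fixtures(spec)
    fasta = out_dir / "regions.fasta"
    table = out_dir / "regions.tsv"
    truth_path = out_dir / "ground_truth.tsv"
    write_regions_fasta(regions, fasta)
    regions_to_table(regions).to_csv(table, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)
    return fasta, table, truth_path


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The bundled demo layout: eight regions across FXN, FMR1 and DMPK.

    VM regions carry planted CCGG* at ~1 copy per 20 bp; the single NM
    region carries AATT* at ~1 copy per 15 bp; AM regions are pure
    background.  GC fraction 0.5 throughout.
    """
    vm_plant = (PlantSpec(pattern="CCGG*", rate=1 / 20),)
    nm_plant = (PlantSpec(pattern="AATT*", rate=1 / 15),)
    return FixtureSpec(
        seed=seed,
        regions=(
            RegionSpec("FXN_VM", "FXN", "VM", 200, 0.5, vm_plant),
            RegionSpec("FXN_AM_1", "FXN", "AM", 300, 0.5),
            RegionSpec("FXN_AM_2", "FXN", "AM", 250, 0.5),
            RegionSpec("FMR1_VM", "FMR1", "VM", 250, 0.5, vm_plant),
            RegionSpec("FMR1_AM", "FMR1", "AM", 400, 0.5),
            RegionSpec("DMPK_VM", "DMPK", "VM", 220, 0.5, vm_plant),
            RegionSpec("DMPK_AM", "DMPK", "AM", 350, 0.5),
            RegionSpec("DMPK_NM", "DMPK", "NM", 230, 0.5, nm_plant),
        ),
    )


def load_fixture_spec(path: Union[str, Path], seed: Optional[int] = None) -> FixtureSpec:
    """Load a fixture spec from YAML; ``seed`` overrides the file's seed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    regions = []
    for entry in raw["regions"]:
        planted = tuple(
            PlantSpec(
                pattern=p["pattern"],
                copies=p.get("copies"),
                rate=p.get("rate"),
            )
            for p in entry.get("planted", [])
        )
        regions.append(
            RegionSpec(
                region_id=entry["region_id"],
                gene=entry["gene"],
                meth_class=entry["meth_class"],
                length_bp=int(entry["length_bp"]),
                gc_fraction=float(entry.get("gc_fraction", 0.5)),
                planted=planted,
            )
        )
    return FixtureSpec(
        seed=int(raw["seed"]) if seed is None else int(seed),
        regions=tuple(regions),
    )
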