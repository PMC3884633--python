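"""Class-level aggregation and discriminating-pattern reports.

For each pattern, per-region proportional frequencies are summed over the
regions of each methylation class, giving three class sums.  Patterns then
discriminate classes in three ways:

* *unique to a class* — nonzero sum in that class, zero in both others;
* *absent in a class* — zero sum there, ranked by the other classes' total
  (with a ``deficit`` variant that ranks by the difference without
  requiring a strict zero);
* *enriched in a class* — strictly larger sum than each other class.

All comparisons use exact rationals; sums are rounded to 6 decimal places
only at output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .notation import pattern_to_regex
from .patterns import FrequencyRecord, WildcardPattern
from .regions import GenomicRegion, MethClass

__all__ = [
    "ClassSummary",
    "sum_by_class",
    "unique_to_class",
    "absent_in_class_ranked",
    "enriched_in_class_ranked",
    "summaries_to_frame",
    "ranking_to_frame",
]

AbsentMode = Literal["absent", "deficit"]


@dataclass(frozen=True)
class ClassSummary:
    """Summed proportional frequencies of one pattern in each class."""

    pattern: str
    sum_vm: Fraction
    sum_am: Fraction
    sum_nm: Fraction

    def class_sum(self, cls: MethClass) -> Fraction:
        return {
            MethClass.VM: self.sum_vm,
            MethClass.AM: self.sum_am,
            MethClass.NM: self.sum_nm,
        }[MethClass(cls)]

    def others_sum(self, cls: MethClass) -> Fraction:
        cls = MethClass(cls)
        return sum(
            (self.class_sum(other) for other in MethClass if other != cls),
            Fraction(0),
        )


def sum_by_class(
    frequency_records: Iterable[FrequencyRecord],
    regions: Sequence[GenomicRegion],
) -> list[ClassSummary]:
    """One summary per pattern appearing in any record, pattern-sorted."""
    class_of = {r.region_id: r.meth_class for r in regions}
    sums: dict[str, dict[MethClass, Fraction]] = {}
    for rec in frequency_records:
        if rec.region_id not in class_of:
            raise KeyError(f"record references unknown region {rec.region_id!r}")
        per = sums.setdefault(
            rec.pattern, {cls: Fraction(0) for cls in MethClass}
        )
        per[class_of[rec.region_id]] += rec.proportional_frequency
    return [
        ClassSummary(
            pattern=pattern,
            sum_vm=per[MethClass.VM],
            sum_am=per[MethClass.AM],
            sum_nm=per[MethClass.NM],
        )
        for pattern, per in sorted(sums.items())
    ]


def _ranked(
    scored: list[tuple[Fraction, ClassSummary]], top_n: Optional[int]
) -> list[ClassSummary]:
    # descending score, ties by pattern text
    scored.sort(key=lambda item: (-item[0], item[1].pattern))
    result = [summary for _, summary in scored]
    return result if top_n is None else result[:top_n]


def unique_to_class(
    summaries: Iterable[ClassSummary],
    cls: MethClass,
    top_n: Optional[int] = None,
) -> list[ClassSummary]:
    """Patterns occurring in ``cls`` (sum > 0) and nowhere else, ranked by
    the class sum descending."""
    cls = MethClass(cls)
    scored = [
        (s.class_sum(cls), s)
        for s in summaries
        if s.class_sum(cls) > 0 and s.others_sum(cls) == 0
    ]
    return _ranked(scored, top_n)


def absent_in_class_ranked(
    summaries: Iterable[ClassSummary],
    cls: MethClass,
    top_n: Optional[int] = None,
    mode: AbsentMode = "absent",
) -> list[ClassSummary]:
    """Patterns that separate ``cls`` from the other two classes by scarcity.

    ``mode="absent"``: sum in ``cls`` is exactly zero; score is the other
    classes' combined sum.  ``mode="deficit"``: no zero requirement; score
    is (others' sum − class sum), so merely-less-frequent patterns rank too.
    """
    cls = MethClass(cls)
    if mode == "absent":
        scored = [
            (s.others_sum(cls), s)
            for s in summaries
            if s.class_sum(cls) == 0 and s.others_sum(cls) > 0
        ]
    elif mode == "deficit":
        scored = [(s.others_sum(cls) - s.class_sum(cls), s) for s in summaries]
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'absent' or 'deficit')")
    return _ranked(scored, top_n)


def enriched_in_class_ranked(
    summaries: Iterable[ClassSummary],
    cls: MethClass,
    top_n: Optional[int] = None,
) -> list[ClassSummary]:
    """Patterns whose ``cls`` sum strictly exceeds each other class's sum."""
    cls = MethClass(cls)
    scored = [
        (s.class_sum(cls), s)
        for s in summaries
        if all(
            s.class_sum(cls) > s.class_sum(other)
            for other in MethClass
            if other != cls
        )
    ]
    return _ranked(scored, top_n)


def summaries_to_frame(summaries: Iterable[ClassSummary]) -> pd.DataFrame:
    """Class-summary table with sums at 6 d.p. and the bracketed regex
    rendering of each pattern alongside."""
    rows = [
        {
            "pattern": s.pattern,
            "pattern_regex": pattern_to_regex(WildcardPattern(s.pattern)),
            "sum_vm": f"{float(s.sum_vm):.6f}",
            "sum_am": f"{float(s.sum_am):.6f}",
            "sum_nm": f"{float(s.sum_nm):.6f}",
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["pattern", "pattern_regex", "sum_vm", "sum_am", "sum_nm"])


def ranking_to_frame(
    ranked: Sequence[ClassSummary], cls: MethClass, mode: str
) -> pd.DataFrame:
    """Discrimination report: rank, pattern, score, and the three sums."""
    cls = MethClass(cls)
    rows = []
    for rank, s in enumerate(ranked, start=1):
        if mode == "absent":
            score = s.others_sum(cls)
        elif mode == "deficit":
            score = s.others_sum(cls) - s.class_sum(cls)
        else:  # unique / enriched rank by the class sum itself
            score = s.class_sum(cls)
        rows.append(
            {
                "rank": rank,
                "pattern": s.pattern,
                "pattern_regex": pattern_to_regex(WildcardPattern(s.pattern)),
                "score": f"{float(score):.6f}",
                "sum_vm": f"{float(s.sum_vm):.6f}",
                "sum_am": f"{float(s.sum_am):.6f}",
                "sum_nm": f"{float(s.sum_nm):.6f}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["rank", "pattern", "pattern_regex", "score", "sum_vm", "sum_am", "sum_nm"],
    )
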