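"""Information-gain decision tree over per-region pattern frequencies.

A C4.5-style greedy tree: instances are regions, attributes are wildcard
patterns, attribute values are per-region proportional frequencies (never
class sums).  Numeric attributes are split binarily at thresholds between
consecutive distinct sorted values; the split maximizing information gain
(entropy reduction, in bits) wins.  Following the C4.5/WEKA convention the
*reported* threshold is the largest observed attribute value not exceeding
the midpoint, so printed thresholds are always attainable data values.

Defaults suit tiny datasets (a handful of regions): no pruning, minimum
leaf size 1, unlimited depth.  Gain ratio is available as an alternative
selection criterion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import pandas as pd

from .regions import GenomicRegion, MethClass

__all__ = [
    "Instance",
    "TreeNode",
    "SplitEvaluation",
    "entropy",
    "best_split",
    "build_tree",
    "classify",
    "training_accuracy",
    "export_tree",
    "parse_tree_json",
    "instances_from_frequencies",
    "instance_matrix",
    "write_arff",
]

Criterion = Literal["infogain", "gainratio"]
Number = Union[int, float, Fraction]

LABELS = [cls.value for cls in MethClass]


@dataclass(frozen=True)
class Instance:
    """One region as a classifier instance: label plus a sparse mapping
    pattern → proportional frequency (missing patterns count as 0)."""

    region_id: str
    label: str
    attributes: Mapping[str, Fraction]

    def value(self, attribute: str) -> Fraction:
        return self.attributes.get(attribute, Fraction(0))


@dataclass(frozen=True)
class SplitEvaluation:
    """Outcome of evaluating one attribute: the gain-maximizing binary
    split, or a degenerate marker for constant attributes."""

    attribute: str
    threshold: Fraction
    information_gain: float
    gain_ratio: float = 0.0
    degenerate: bool = False


@dataclass
class TreeNode:
    """Internal node (attribute, threshold, two children) or leaf
    (label, class_counts).  Instances with value ≤ threshold go left."""

    attribute: Optional[str] = None
    threshold: Optional[Fraction] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    label: Optional[str] = None
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TreeNode):
            return NotImplemented
        return (
            self.attribute == other.attribute
            and self.threshold == other.threshold
            and self.label == other.label
            and self.class_counts == other.class_counts
            and self.left == other.left
            and self.right == other.right
        )


def entropy(class_counts: Mapping[str, Number]) -> float:
    """Shannon entropy in bits: ``H = -Σ p_i log2 p_i`` over nonzero classes."""
    total = sum(class_counts.values())
    if total <= 0:
        raise ValueError("entropy undefined for all-zero class counts")
    h = 0.0
    for count in class_counts.values():
        if count > 0:
            p = count / total
            h -= p * math.log2(p)
    return h


def _counts(instances: Sequence[Instance]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for inst in instances:
        counts[inst.label] = counts.get(inst.label, 0) + 1
    return counts


def best_split(instances: Sequence[Instance], attribute: str) -> SplitEvaluation:
    """Gain-maximizing binary split of one numeric attribute.

    Candidate split points lie between consecutive distinct sorted values;
    the returned ``threshold`` is the lower of each such pair (the largest
    observed value not exceeding the midpoint).  A constant attribute gives
    gain 0 with ``degenerate=True``.  Gain ties prefer the lower threshold.
    """
    if len(instances) < 2:
        raise ValueError("best_split needs at least 2 instances")
    pairs = sorted(
        ((inst.value(attribute), inst.label) for inst in instances),
        key=lambda p: p[0],
    )
    values = sorted({v for v, _ in pairs})
    if len(values) == 1:
        return SplitEvaluation(
            attribute=attribute,
            threshold=values[0],
            information_gain=0.0,
            gain_ratio=0.0,
            degenerate=True,
        )

    parent_entropy = entropy(_counts(instances))
    n = len(pairs)
    best: Optional[SplitEvaluation] = None
    left_counts: dict[str, int] = {}
    idx = 0
    for threshold in values[:-1]:
        while idx < n and pairs[idx][0] <= threshold:
            label = pairs[idx][1]
            left_counts[label] = left_counts.get(label, 0) + 1
            idx += 1
        n_left = idx
        n_right = n - idx
        right_counts = {
            label: total - left_counts.get(label, 0)
            for label, total in _counts(instances).items()
        }
        child_entropy = (
            n_left / n * entropy(left_counts) + n_right / n * entropy(right_counts)
        )
        gain = parent_entropy - child_entropy
        split_info = entropy({"left": n_left, "right": n_right})
        ratio = gain / split_info if split_info > 0 else 0.0
        candidate = SplitEvaluation(
            attribute=attribute,
            threshold=threshold,
            information_gain=gain,
            gain_ratio=ratio,
        )
        if best is None or gain > best.information_gain + 1e-12:
            best = candidate
    assert best is not None
    return best


@dataclass(frozen=True)
class TreeConfig:
    min_leaf: int = 1
    max_depth: Optional[int] = None
    criterion: Criterion = "infogain"


def _leaf(instances: Sequence[Instance]) -> TreeNode:
    counts = _counts(instances)
    top = max(counts.values())
    label = sorted(lbl for lbl, c in counts.items() if c == top)[0]
    return TreeNode(label=label, class_counts=counts)


def build_tree(
    instances: Sequence[Instance],
    attributes: Optional[Sequence[str]] = None,
    config: TreeConfig = TreeConfig(),
) -> TreeNode:
    """Recursive greedy construction.

    Stops on node purity, zero best gain, exhausted depth, or a split that
    would violate ``min_leaf``.  Leaf label is the majority class, ties to
    the lexicographically first label.  Attribute ties break by score, then
    pattern text, then lower threshold, so building is deterministic and
    independent of instance order.
    """
    if not instances:
        raise ValueError("cannot build a tree from zero instances")
    if attributes is None:
        attributes = sorted({a for inst in instances for a in inst.attributes})

    def grow(subset: Sequence[Instance], depth: int) -> TreeNode:
        counts = _counts(subset)
        if len(counts) == 1 or len(subset) < 2:
            return _leaf(subset)
        if config.max_depth is not None and depth >= config.max_depth:
            return _leaf(subset)

        best_eval: Optional[SplitEvaluation] = None
        for attribute in sorted(attributes):
            ev = best_split(subset, attribute)
            if ev.degenerate:
                continue
            score = ev.gain_ratio if config.criterion == "gainratio" else ev.information_gain
            if best_eval is None:
                best_eval, best_score = ev, score
                continue
            if score > best_score + 1e-12:
                best_eval, best_score = ev, score
            elif abs(score - best_score) <= 1e-12:
                # tie: lexicographic attribute, then lower threshold
                if (ev.attribute, ev.threshold) < (best_eval.attribute, best_eval.threshold):
                    best_eval = ev

        if best_eval is None or best_eval.information_gain <= 1e-12:
            return _leaf(subset)

        left = [i for i in subset if i.value(best_eval.attribute) <= best_eval.threshold]
        right = [i for i in subset if i.value(best_eval.attribute) > best_eval.threshold]
        if len(left) < config.min_leaf or len(right) < config.min_leaf:
            return _leaf(subset)
        return TreeNode(
            attribute=best_eval.attribute,
            threshold=best_eval.threshold,
            left=grow(left, depth + 1),
            right=grow(right, depth + 1),
            class_counts=counts,
        )

    return grow(list(instances), 0)


def classify(tree: TreeNode, instance: Instance) -> str:
    """Deterministic root-to-leaf descent; boundary values go left (≤)."""
    node = tree
    while not node.is_leaf:
        if instance.value(node.attribute) <= node.threshold:
            node = node.left
        else:
            node = node.right
    return node.label


def training_accuracy(tree: TreeNode, instances: Sequence[Instance]) -> float:
    correct = sum(1 for inst in instances if classify(tree, inst) == inst.label)
    return correct / len(instances)


def export_tree(tree: TreeNode, format: Literal["text", "json"] = "text") -> str:
    """Serialize a tree.

    ``text``: one node per line, indented by depth, thresholds at 6 d.p.
    ``json``: lossless (thresholds as exact rational strings); round-trips
    through :func:`parse_tree_json`.
    """
    if format == "text":
        lines: list[str] = []

        def walk(node: TreeNode, depth: int, prefix: str) -> None:
            pad = "|   " * depth
            if node.is_leaf:
                counts = ", ".join(f"{k}:{v}" for k, v in sorted(node.class_counts.items()))
                lines.append(f"{pad}{prefix}{node.label} ({counts})")
            else:
                lines.append(f"{pad}{prefix}{node.attribute} <= {float(node.threshold):.6f}?")
                walk(node.left, depth + 1, "yes: ")
                walk(node.right, depth + 1, "no:  ")

        walk(tree, 0, "")
        return "\n".join(lines) + "\n"
    if format == "json":
        return json.dumps(_to_dict(tree), indent=2) + "\n"
    raise ValueError(f"unknown format {format!r}")


def _to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"label": node.label, "class_counts": node.class_counts}
    return {
        "attribute": node.attribute,
        "threshold": str(node.threshold),
        "class_counts": node.class_counts,
        "left": _to_dict(node.left),
        "right": _to_dict(node.right),
    }


def parse_tree_json(text: str) -> TreeNode:
    def from_dict(d: dict) -> TreeNode:
        if "attribute" in d:
            return TreeNode(
                attribute=d["attribute"],
                threshold=Fraction(d["threshold"]),
                class_counts={k: int(v) for k, v in d.get("class_counts", {}).items()},
                left=from_dict(d["left"]),
                right=from_dict(d["right"]),
            )
        return TreeNode(
            label=d["label"],
            class_counts={k: int(v) for k, v in d.get("class_counts", {}).items()},
        )

    return from_dict(json.loads(text))


def instances_from_frequencies(
    frequency_records: Iterable,
    regions: Sequence[GenomicRegion],
) -> list[Instance]:
    """Turn per-region frequency records into classifier instances,
    zero-imputing unobserved patterns (sparsely)."""
    attrs: dict[str, dict[str, Fraction]] = {r.region_id: {} for r in regions}
    for rec in frequency_records:
        attrs[rec.region_id][rec.pattern] = rec.proportional_frequency
    return [
        Instance(
            region_id=r.region_id,
            label=r.meth_class.value,
            attributes=attrs[r.region_id],
        )
        for r in regions
    ]


def instance_matrix(
    instances: Sequence[Instance],
    attributes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Dense regions × patterns matrix of proportional frequencies (floats),
    with region_id index and a trailing ``meth_class`` column."""
    if attributes is None:
        attributes = sorted({a for inst in instances for a in inst.attributes})
    data = {
        attr: [float(inst.value(attr)) for inst in instances] for attr in attributes
    }
    frame = pd.DataFrame(data, index=[inst.region_id for inst in instances])
    frame.index.name = "region_id"
    frame["meth_class"] = [inst.label for inst in instances]
    return frame


def write_arff(
    instances: Sequence[Instance],
    path,
    relation: str = "methylation_regions",
    attributes: Optional[Sequence[str]] = None,
) -> None:
    """ARFF export so the instance matrix can be cross-checked in external
    ML tools.  Pattern names are quoted (they contain ``*``)."""
    if attributes is None:
        attributes = sorted({a for inst in instances for a in inst.attributes})
    with open(path, "w") as fh:
        fh.write(f"@RELATION {relation}\n\n")
        for attr in attributes:
            fh.write(f"@ATTRIBUTE '{attr}' NUMERIC\n")
        fh.write(f"@ATTRIBUTE meth_class {{{','.join(LABELS)}}}\n\n@DATA\n")
        for inst in instances:
            values = ",".join(f"{float(inst.value(a)):.6f}" for a in attributes)
            fh.write(f"{values},{inst.label}\n")
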