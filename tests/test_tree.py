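"""Entropy, split search, tree growth, classification and serialization."""

import math
from fractions import Fraction

import numpy as np
import pytest

from methylmotif import (
    Instance,
    TreeConfig,
    TreeNode,
    best_split,
    build_tree,
    classify,
    entropy,
    export_tree,
    parse_tree_json,
    training_accuracy,
    write_arff,
)


def inst(region_id, label, **attrs):
    return Instance(
        region_id=region_id,
        label=label,
        attributes={k: Fraction(v).limit_denominator(10**6) for k, v in attrs.items()},
    )


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"A": 4}, 0.0),
        ({"A": 1, "B": 1}, 1.0),
        ({"A": 2, "B": 1, "C": 1}, 1.5),
        ({"A": 3, "B": 1}, -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))),
    ],
)
def test_entropy_closed_forms(counts, expected):
    assert entropy(counts) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_all_zero():
    with pytest.raises(ValueError):
        entropy({"A": 0, "B": 0})


def test_best_split_perfect_binary():
    instances = [
        inst("a", "X", p=0),
        inst("b", "X", p=0),
        inst("c", "Y", p=1),
        inst("d", "Y", p=1),
    ]
    ev = best_split(instances, "p")
    assert ev.information_gain == pytest.approx(1.0)
    # reported threshold is the largest observed value below the split
    assert ev.threshold == 0
    assert not ev.degenerate


def test_best_split_constant_attribute_is_degenerate():
    instances = [inst("a", "X", p=3), inst("b", "Y", p=3)]
    ev = best_split(instances, "p")
    assert ev.degenerate and ev.information_gain == 0.0


def exhaustive_split_oracle(instances, attribute):
    """Independent oracle: evaluate every candidate threshold directly."""
    values = sorted({float(i.value(attribute)) for i in instances})
    parent = entropy(
        {lbl: sum(1 for i in instances if i.label == lbl) for lbl in {i.label for i in instances}}
    )
    best_gain, best_thr = -1.0, None
    for thr in values[:-1]:
        left = [i for i in instances if float(i.value(attribute)) <= thr]
        right = [i for i in instances if float(i.value(attribute)) > thr]
        child = 0.0
        for part in (left, right):
            counts = {lbl: sum(1 for i in part if i.label == lbl) for lbl in {i.label for i in part}}
            child += len(part) / len(instances) * entropy(counts)
        gain = parent - child
        if gain > best_gain + 1e-12:
            best_gain, best_thr = gain, thr
    return best_gain, best_thr


def test_best_split_matches_exhaustive_oracle():
    rng = np.random.default_rng(11)
    labels = ["AM", "VM", "NM"]
    for _ in range(40):
        instances = [
            inst(f"r{i}", labels[int(rng.integers(3))], p=round(float(rng.random()), 3))
            for i in range(8)
        ]
        if len({float(i.value("p")) for i in instances}) == 1:
            continue
        ev = best_split(instances, "p")
        gain, thr = exhaustive_split_oracle(instances, "p")
        assert ev.information_gain == pytest.approx(gain, abs=1e-12)
        assert float(ev.threshold) == pytest.approx(thr)


def test_build_tree_root_is_separating_attribute():
    """A pattern with frequency > 0 only in VM regions, against noisy
    non-separating attributes, must become the root."""
    instances = [
        inst("vm1", "VM", P="0.05", Q="0.01"),
        inst("vm2", "VM", P="0.04", Q="0.03"),
        inst("am1", "AM", P=0, Q="0.02"),
        inst("am2", "AM", P=0, Q="0.01"),
    ]
    tree = build_tree(instances)
    assert tree.attribute == "P"
    assert tree.left.is_leaf and tree.right.is_leaf
    assert training_accuracy(tree, instances) == 1.0


def test_build_tree_stops_on_purity_and_singletons():
    single = build_tree([inst("r", "NM", P=1)])
    assert single.is_leaf and single.label == "NM"
    pure = build_tree([inst("a", "AM", P=0), inst("b", "AM", P=1)])
    assert pure.is_leaf and pure.label == "AM"


def test_leaf_majority_tie_is_lexicographic():
    # no attribute separates; VM vs AM tie -> AM (lexicographically first)
    tree = build_tree([inst("a", "VM", P=1), inst("b", "AM", P=1)])
    assert tree.is_leaf and tree.label == "AM"


def test_boundary_instance_goes_left():
    instances = [
        inst("a", "X", p=0),
        inst("b", "X", p=0),
        inst("c", "Y", p=1),
    ]
    tree = build_tree(instances)
    assert tree.threshold == 0
    assert classify(tree, inst("q", "?", p=0)) == "X"  # exactly at threshold
    assert classify(tree, inst("q", "?", p="0.5")) == "Y"


def test_training_consistency_on_separable_data():
    rng = np.random.default_rng(5)
    instances = []
    for i in range(4):
        instances.append(inst(f"v{i}", "VM", P=round(0.05 + 0.01 * float(rng.random()), 4), Q=round(float(rng.random()), 4)))
        instances.append(inst(f"a{i}", "AM", P=round(0.01 * float(rng.random()), 4), Q=round(float(rng.random()), 4)))
    tree = build_tree(instances)
    assert training_accuracy(tree, instances) == 1.0
    for item in instances:
        assert classify(tree, item) == item.label


def test_gain_bounded_by_parent_entropy():
    rng = np.random.default_rng(3)
    for _ in range(30):
        instances = [
            inst(f"r{i}", "AB"[int(rng.integers(2))], p=round(float(rng.random()), 2))
            for i in range(6)
        ]
        if len({float(i.value("p")) for i in instances}) == 1:
            continue
        parent = entropy(
            {lbl: sum(1 for i in instances if i.label == lbl) for lbl in {i.label for i in instances}}
        )
        ev = best_split(instances, "p")
        assert -1e-12 <= ev.information_gain <= parent + 1e-12


def test_sklearn_agrees_on_separable_training_data():
    """Independent cross-check: an entropy-criterion CART tree reaches the
    same (perfect) training classification on the same matrix."""
    from sklearn.tree import DecisionTreeClassifier

    instances = [
        inst("v1", "VM", P="0.05", Q="0.01"),
        inst("v2", "VM", P="0.04", Q="0.02"),
        inst("a1", "AM", P=0, Q="0.02"),
        inst("a2", "AM", P=0, Q="0.03"),
        inst("n1", "NM", P=0, Q="0.10"),
    ]
    ours = build_tree(instances)
    X = [[float(i.value("P")), float(i.value("Q"))] for i in instances]
    y = [i.label for i in instances]
    sk = DecisionTreeClassifier(criterion="entropy", random_state=0).fit(X, y)
    assert training_accuracy(ours, instances) == 1.0
    assert list(sk.predict(X)) == y
    assert [classify(ours, i) for i in instances] == y


def test_export_text_shape_and_threshold_rendering():
    tree = TreeNode(
        attribute="AATT*",
        threshold=Fraction(3697, 1000000),
        left=TreeNode(label="AM", class_counts={"AM": 4, "VM": 3}),
        right=TreeNode(label="NM", class_counts={"NM": 1}),
        class_counts={"AM": 4, "VM": 3, "NM": 1},
    )
    text = export_tree(tree, "text")
    assert len(text.strip().splitlines()) == 3  # node + 2 leaves
    assert "0.003697" in text


def test_json_roundtrip_random_trees():
    rng = np.random.default_rng(17)

    def random_tree(depth):
        if depth == 0 or rng.random() < 0.4:
            label = ["AM", "VM", "NM"][int(rng.integers(3))]
            return TreeNode(label=label, class_counts={label: int(rng.integers(1, 5))})
        return TreeNode(
            attribute=f"P{int(rng.integers(10))}",
            threshold=Fraction(int(rng.integers(1, 100)), 1000),
            left=random_tree(depth - 1),
            right=random_tree(depth - 1),
            class_counts={"AM": 1, "VM": 1},
        )

    for _ in range(20):
        tree = random_tree(3)
        assert parse_tree_json(export_tree(tree, "json")) == tree


def test_arff_roundtrip_via_scipy(tmp_path):
    from scipy.io import arff as scipy_arff

    instances = [
        inst("v1", "VM", **{"CCGG*": "0.05", "AATT*": "0.01"}),
        inst("a1", "AM", **{"CCGG*": 0, "AATT*": "0.02"}),
    ]
    path = tmp_path / "demo.arff"
    write_arff(instances, path)
    data, meta = scipy_arff.loadarff(path)
    assert len(data) == 2
    assert [x.decode() for x in data["meth_class"]] == ["VM", "AM"]
    first = data[0]
    assert float(first[0]) == pytest.approx(0.01)  # AATT* sorted first


def test_gain_ratio_criterion_runs():
    instances = [
        inst("v1", "VM", P="0.05"),
        inst("v2", "VM", P="0.04"),
        inst("a1", "AM", P=0),
    ]
    tree = build_tree(instances, config=TreeConfig(criterion="gainratio"))
    assert training_accuracy(tree, instances) == 1.0
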