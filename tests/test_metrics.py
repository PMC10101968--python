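"""Confusion-matrix statistics: published-table exactness and oracles."""

import numpy as np
import pytest

from cytotomo.metrics import (
    ConfusionMatrix,
    binary_metrics,
    cm_from_recalls,
    confusion_matrix,
    multiclass_metrics,
    round_half_up,
)

# the unique 3x3 hierarchical test matrix consistent with the published
# per-class recalls and precisions (row sums 47/122/60)
HIER_3D = ConfusionMatrix(
    np.array([[45, 2, 0], [4, 114, 4], [0, 1, 59]]), ("MC", "NB", "OC")
)
STAGE_A_3D = ConfusionMatrix(np.array([[45, 2], [4, 178]]), ("MC", "tumor"))
STAGE_B_3D = ConfusionMatrix(np.array([[118, 4], [1, 59]]), ("NB", "OC"))


def brute_force_binary(tp, fn, fp, tn):
    """Independent direct evaluation of all nine statistics."""
    import math

    total = tp + fn + fp + tn
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    ppv = tp / (tp + fp)
    npv = tn / (tn + fn)
    return {
        "accuracy": (tp + tn) / total,
        "recall": tpr,
        "specificity": tnr,
        "precision": ppv,
        "npv": npv,
        "balanced_accuracy": (tpr + tnr) / 2,
        "f1": 2 * tp / (2 * tp + fp + fn),
        "mcc": (tp * tn - fp * fn)
        / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)),
        "fowlkes_mallows": math.sqrt(ppv * tpr),
    }


def test_rounding_half_up():
    # 93.75 must print as 93.8, not banker's 93.7
    assert round_half_up(93.75) == 93.8
    assert round_half_up(95.744680) == 95.7
    assert round_half_up(-1.25) == -1.3


def test_confusion_matrix_counting():
    cm = confusion_matrix(
        ["a", "a", "b", "b", "b"], ["a", "b", "b", "b", "a"], ("a", "b")
    )
    assert cm.counts.tolist() == [[1, 1], [1, 2]]
    with pytest.raises(ValueError, match="unknown"):
        confusion_matrix(["a", "c"], ["a", "a"], ("a", "b"))


def test_perfect_and_swapped_predictions():
    perfect = confusion_matrix(["x"] * 10 + ["y"] * 10, ["x"] * 10 + ["y"] * 10, ("x", "y"))
    assert np.all(perfect.counts == np.diag([10, 10]))
    report = binary_metrics(perfect)
    assert report.accuracy == 100.0
    assert all(v == 100.0 for v in report.per_class["x"].values())
    swapped = confusion_matrix(["x"] * 5 + ["y"] * 5, ["y"] * 5 + ["x"] * 5, ("x", "y"))
    assert np.all(np.diag(swapped.counts) == 0)


@pytest.mark.parametrize(
    "cm, checks",
    [
        (  # stage A, 3D: MC vs tumor
            STAGE_A_3D,
            {
                ("accuracy",): 97.4,
                ("MC", "recall"): 95.7,
                ("tumor", "recall"): 97.8,
                ("MC", "precision"): 91.8,
                ("tumor", "precision"): 98.9,
                ("MC", "npv"): 98.9,
                ("MC", "balanced_accuracy"): 96.8,
                ("MC", "f1"): 93.8,
                ("tumor", "f1"): 98.3,
                ("MC", "mcc"): 92.1,
                ("MC", "fowlkes_mallows"): 93.8,
                ("tumor", "fowlkes_mallows"): 98.3,
            },
        ),
        (  # stage B, 3D: NB vs OC
            STAGE_B_3D,
            {
                ("accuracy",): 97.3,
                ("NB", "recall"): 96.7,
                ("OC", "recall"): 98.3,
                ("NB", "precision"): 99.2,
                ("OC", "precision"): 93.7,
                ("NB", "f1"): 97.9,
                ("NB", "mcc"): 93.9,
                ("NB", "balanced_accuracy"): 97.5,
            },
        ),
    ],
)
def test_binary_metrics_reproduce_published_tables(cm, checks):
    report = binary_metrics(cm)
    for key, expected in checks.items():
        got = report.accuracy if key == ("accuracy",) else report.per_class[key[0]][key[1]]
        assert got == expected, f"{key}: {got} != {expected}"


def test_multiclass_metrics_reproduce_hierarchical_table():
    report = multiclass_metrics(HIER_3D)
    assert report.accuracy == 95.2
    assert report.per_class["MC"]["recall"] == 95.7
    assert report.per_class["NB"]["recall"] == 93.4
    assert report.per_class["OC"]["recall"] == 98.3
    assert report.per_class["MC"]["precision"] == 91.8
    assert report.per_class["NB"]["precision"] == 97.4
    assert report.per_class["OC"]["precision"] == 93.7
    assert report.per_class["MC"]["mcc"] == 92.1


def test_overall_accuracy_depends_only_on_diagonal():
    # 2D hierarchical baseline: diagonal (30, 95, 49) over (47, 122, 60)
    for off in ([[0, 10, 7], [20, 0, 7], [6, 5, 0]], [[0, 17, 0], [27, 0, 0], [11, 0, 0]]):
        counts = np.array(off)
        np.fill_diagonal(counts, (30, 95, 49))
        cm = ConfusionMatrix(counts, ("MC", "NB", "OC"))
        assert multiclass_metrics(cm).accuracy == 76.0


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        tp=st.integers(0, 500),
        fn=st.integers(0, 500),
        fp=st.integers(0, 500),
        tn=st.integers(1, 500),
    )
    def test_binary_metrics_match_brute_force_property(tp, fn, fp, tn):
        """Any non-degenerate 2x2 matrix agrees with direct evaluation."""
        report = binary_metrics(
            ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), ("pos", "neg"))
        )
        if min(tp + fn, tp + fp, tn + fp, tn + fn) == 0:
            return  # undefined statistics covered elsewhere
        oracle = brute_force_binary(tp, fn, fp, tn)
        for name, value in oracle.items():
            assert report.per_class["pos"][name] == pytest.approx(
                round_half_up(100 * value), abs=1e-9
            )
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_binary_metrics_match_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        tp, fn, fp, tn = rng.integers(1, 200, 4)
        report = binary_metrics(
            ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), ("pos", "neg"))
        )
        oracle = brute_force_binary(int(tp), int(fn), int(fp), int(tn))
        for name, value in oracle.items():
            assert report.per_class["pos"][name] == pytest.approx(
                round_half_up(100 * value), abs=1e-12
            )


def test_binary_symmetry_swaps_tpr_tnr_and_ppv_npv():
    rng = np.random.default_rng(1)
    for _ in range(50):
        tp, fn, fp, tn = rng.integers(1, 100, 4)
        report = binary_metrics(
            ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), ("c1", "c2"))
        )
        assert report.per_class["c1"]["recall"] == report.per_class["c2"]["specificity"]
        assert report.per_class["c1"]["npv"] == report.per_class["c2"]["precision"]


def test_zero_denominator_reported_as_undefined():
    cm = ConfusionMatrix(np.array([[0, 0], [3, 7]]), ("pos", "neg"))
    report = binary_metrics(cm)
    assert report.per_class["pos"]["recall"] is None
    assert any(k.startswith("pos.") for k in report.undefined)


@pytest.mark.parametrize(
    "recalls, sizes, expected",
    [
        ((95.7, 97.8), (47, 182), [[45, 2], [4, 178]]),
        ((96.7, 98.3), (122, 60), [[118, 4], [1, 59]]),
        ((100.0, 100.0), (12, 34), [[12, 0], [0, 34]]),
    ],
)
def test_cm_from_recalls_reconstruction(recalls, sizes, expected):
    cm = cm_from_recalls(recalls, sizes)
    assert cm.counts.tolist() == expected


def test_cm_from_recalls_rejects_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        cm_from_recalls((101.0, 50.0), (10, 10))


def test_reconstructed_stage_a_matrix_reproduces_accuracy():
    # the reconstruction is validated by reproducing the printed accuracy
    cm = cm_from_recalls((95.7, 97.8), (47, 182), ("MC", "tumor"))
    assert binary_metrics(cm).accuracy == 97.4
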