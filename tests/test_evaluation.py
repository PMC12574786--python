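import math

import pandas as pd
import pytest

from odpipeline.evaluation import (
    AnnotationSet,
    ClassMetrics,
    ConfusionMatrix,
    class_metrics,
    cohen_kappa,
    confusion,
    evaluate_annotations,
    macro_average,
    round_display,
)


@pytest.mark.parametrize(
    ("a", "b", "expected"),
    [
        ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
        ([1, 1, 0, 0], [1, 0, 1, 0], 0.0),  # po = pe = 0.5
        ([1, 1, 0, 0], [0, 0, 1, 1], -1.0),  # po = 0, pe = 0.5
    ],
)
def test_cohen_kappa_hand_values(a, b, expected):
    assert cohen_kappa(a, b) == pytest.approx(expected, abs=1e-12)


def test_cohen_kappa_symmetric_and_validated():
    a, b = [1, 0, 1, 0, 1], [1, 1, 0, 0, 1]
    assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a), abs=1e-12)
    with pytest.raises(ValueError, match="length"):
        cohen_kappa([1, 0], [1])
    with pytest.raises(ValueError, match="binary"):
        cohen_kappa([2, 0], [1, 0])


def test_cohen_kappa_degenerate_marginals():
    # constant identical vectors: perfect agreement short-circuits to 1
    assert cohen_kappa([1, 1], [1, 1]) == 1.0
    # constant but opposite vectors: po = 0, pe = 0 -> kappa 0
    assert cohen_kappa([1, 1], [0, 0]) == 0.0


def test_confusion_counts():
    cm = confusion([1, 0], [1, 0])
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)
    zeros = confusion([0] * 5, [0] * 5)
    assert zeros.tn == 5 and zeros.n == 5
    with pytest.raises(ValueError):
        confusion([1], [1, 0])


def test_confusion_from_vectors_matches_metrics():
    """class_metrics agrees with brute-force recomputation from raw labels."""
    system = [1, 1, 0, 0, 1, 0, 1, 0]
    truth = [1, 0, 0, 1, 1, 0, 1, 1]
    cm = confusion(system, truth)
    m = class_metrics(cm)
    n = len(truth)
    assert m.prevalence == pytest.approx(sum(truth) / n)
    tp = sum(s and t for s, t in zip(system, truth))
    assert m.sensitivity == pytest.approx(tp / sum(truth))
    assert m.precision == pytest.approx(tp / sum(system))
    assert m.prevalence * cm.n == pytest.approx(round(m.prevalence * cm.n))


def test_antidepressant_row_metrics():
    # tool missed 2 of 4 anti-depressants on n=120, no false alarms
    m = class_metrics(ConfusionMatrix(tp=2, fp=0, fn=2, tn=116))
    assert m.display() == {
        "prevalence": 0.03,
        "sensitivity": 0.5,
        "precision": 1.0,
        "npv": 0.98,
        "f1": 0.67,
    }


def test_perfect_class_metrics():
    m = class_metrics(ConfusionMatrix(tp=90, fp=0, fn=0, tn=30))
    assert (m.sensitivity, m.precision, m.npv, m.f1) == (1.0, 1.0, 1.0, 1.0)
    assert m.prevalence == 0.75


def test_degenerate_denominators_flagged_not_zeroed():
    m = class_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
    assert m.sensitivity is None and m.precision is None and m.f1 is None
    assert m.npv == 1.0
    assert round_display(None) is None


def test_macro_average_known_values():
    perfect = ClassMetrics(0.3, 1.0, 1.0, 1.0, 1.0)
    antidep = class_metrics(ConfusionMatrix(2, 0, 2, 116))
    macro = macro_average([perfect] * 4 + [antidep])
    assert round_display(macro.f1) == 0.93
    assert round_display(macro.sensitivity) == 0.90
    single = macro_average([antidep])
    assert single == antidep


def test_macro_average_excludes_undefined_pairwise():
    defined = ClassMetrics(0.5, 1.0, 1.0, 1.0, 1.0)
    partial = ClassMetrics(0.0, None, None, 1.0, None)
    macro = macro_average([defined, partial])
    assert macro.sensitivity == 1.0  # only the defined class contributes
    assert macro.npv == 1.0
    assert macro.prevalence == 0.25


def test_round_display_half_up():
    assert round_display(0.665, 2) == 0.67
    assert round_display(0.6666666, 2) == 0.67
    assert round_display(80.468, 1) == pytest.approx(80.5)


def _annotation_frame() -> pd.DataFrame:
    rows = []
    for i, (a, b, cons, sys) in enumerate(
        [(1, 1, 1, 1), (1, 0, 1, 1), (0, 0, 0, 0), (1, 1, 1, 0)]
    ):
        rows.append(
            {
                "case_id": f"C{i}",
                "class": "opioid",
                "annotator_a": a,
                "annotator_b": b,
                "consensus": cons,
                "system": sys,
            }
        )
    return pd.DataFrame(rows)


def test_annotation_set_and_evaluate():
    table = evaluate_annotations(AnnotationSet(_annotation_frame()))
    assert list(table["indicator"]) == ["opioid", "macro average"]
    row = table.iloc[0]
    # system vs consensus: tp=2, fn=1, tn=1 -> sensitivity 2/3
    assert row["sensitivity"] == pytest.approx(2 / 3)
    assert row["precision"] == 1.0
    macro = table.iloc[1]
    assert macro["sensitivity"] == pytest.approx(2 / 3)


def test_annotation_set_validation():
    frame = _annotation_frame().drop(columns="system")
    with pytest.raises(ValueError, match="system"):
        AnnotationSet(frame)
    bad = _annotation_frame()
    bad.loc[0, "consensus"] = 7
    with pytest.raises(ValueError, match="non-binary"):
        AnnotationSet(bad)


def test_full_printed_table_reconstruction():
    """The five implied confusion matrices reproduce the printed evaluation
    table at 2-decimal display (per-class rows)."""
    matrices = {
        "ethanol": ConfusionMatrix(36, 0, 0, 84),
        "stimulant": ConfusionMatrix(48, 0, 0, 72),
        "opiate": ConfusionMatrix(90, 0, 0, 30),
        "benzodiazepine": ConfusionMatrix(18, 0, 0, 102),
        "anti-depressant": ConfusionMatrix(2, 0, 2, 116),
    }
    printed = {
        "ethanol": (0.30, 1.0, 1.0, 1.0, 1.0),
        "stimulant": (0.40, 1.0, 1.0, 1.0, 1.0),
        "opiate": (0.75, 1.0, 1.0, 1.0, 1.0),
        "benzodiazepine": (0.15, 1.0, 1.0, 1.0, 1.0),
        "anti-depressant": (0.03, 0.5, 1.0, 0.98, 0.67),
    }
    for label, cm in matrices.items():
        assert cm.n == 120
        d = class_metrics(cm).display()
        assert (
            d["prevalence"],
            d["sensitivity"],
            d["precision"],
            d["npv"],
            d["f1"],
        ) == printed[label], label
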