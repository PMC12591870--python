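"""Detection-metric tests against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pytest

from rotoloc.geometry import Box, ObjectClass
from rotoloc.metrics import (
    GroundTruthSet,
    MatchResult,
    UndefinedMetricError,
    average_precision_50,
    confusion_metrics,
    evaluate,
    match_detections,
    patient_fold_split,
)


def B(x, y, L, H, cls=ObjectClass.TUMOR, conf=1.0):
    return Box(x, y, L, H, class_id=cls, confidence=conf)


def gt_of(images: dict, patients=None):
    return GroundTruthSet(
        boxes=images,
        patients=patients or {k: f"p_{k}" for k in images},
    )


def brute_force_ap(records, n_gt):
    """All-points-interpolated AP by explicit curve enumeration.

    ``records``: (confidence, is_tp) pairs. Walk thresholds in confidence
    order, collect (recall, precision) points, integrate the upper
    envelope piecewise -- completely independent of the vectorized path.
    """
    records = sorted(records, key=lambda r: -r[0])
    points = []
    tp = fp = 0
    for _, is_tp in records:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        if r == prev_r:
            continue
        best_p = max(p for rr, p in points if rr >= r)
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap


class TestMatching:
    def test_exact_match(self):
        gts = gt_of({"a": [B(10, 10, 50, 40)]})
        m = match_detections({"a": [B(10, 10, 50, 40)]}, gts)
        assert (m.tp[ObjectClass.TUMOR], m.fp[ObjectClass.TUMOR], m.fn[ObjectClass.TUMOR]) == (1, 0, 0)

    def test_disjoint_boxes(self):
        gts = gt_of({"a": [B(10, 10, 50, 40)]})
        m = match_detections({"a": [B(300, 300, 50, 40)]}, gts)
        assert (m.tp[ObjectClass.TUMOR], m.fp[ObjectClass.TUMOR], m.fn[ObjectClass.TUMOR]) == (0, 1, 1)

    def test_greedy_one_to_one(self):
        """Two overlapping predictions, one ground truth: one TP, one FP."""
        gts = gt_of({"a": [B(10, 10, 50, 40)]})
        preds = {"a": [B(12, 10, 50, 40, conf=0.9), B(8, 10, 50, 40, conf=0.8)]}
        m = match_detections(preds, gts)
        assert (m.tp[ObjectClass.TUMOR], m.fp[ObjectClass.TUMOR]) == (1, 1)

    def test_count_conservation(self, rng):
        """TP + FN equals the ground-truth count per class, always."""
        for _ in range(30):
            gts_boxes, preds = {}, {}
            for img in range(4):
                key = f"i{img}"
                gts_boxes[key] = [
                    B(rng.uniform(0, 500), rng.uniform(0, 500), 40, 30,
                      cls=ObjectClass(int(rng.integers(0, 2))))
                    for _ in range(rng.integers(0, 4))
                ]
                preds[key] = [
                    B(rng.uniform(0, 500), rng.uniform(0, 500), 40, 30,
                      cls=ObjectClass(int(rng.integers(0, 2))),
                      conf=float(rng.uniform(0.1, 1)))
                    for _ in range(rng.integers(0, 4))
                ]
            gts = gt_of(gts_boxes)
            m = match_detections(preds, gts)
            for cls in ObjectClass:
                assert m.tp[cls] + m.fn[cls] == gts.class_count(cls)

    def test_tn_image_level_convention(self):
        gts = gt_of({"a": [B(1, 1, 5, 5, cls=ObjectClass.SLOT)], "b": []})
        m = match_detections({"a": [], "b": []}, gts)
        assert m.tn[ObjectClass.TUMOR] == 2  # neither image has tumors
        assert m.tn[ObjectClass.SLOT] == 1   # only image b is slot-free

    def test_threshold_validation(self):
        gts = gt_of({"a": []})
        with pytest.raises(ValueError):
            match_detections({}, gts, iou_threshold=1.5)


class TestAveragePrecision:
    def test_perfect_detector(self):
        gts = gt_of({"a": [B(10, 10, 50, 40)], "b": [B(5, 5, 30, 30)]})
        preds = {k: list(v) for k, v in gts.boxes.items()}
        assert average_precision_50(preds, gts, ObjectClass.TUMOR) == 1.0

    def test_empty_detector(self):
        gts = gt_of({"a": [B(10, 10, 50, 40)]})
        assert average_precision_50({}, gts, ObjectClass.TUMOR) == 0.0

    def test_undefined_without_ground_truth(self):
        gts = gt_of({"a": []})
        with pytest.raises(UndefinedMetricError):
            average_precision_50({}, gts, ObjectClass.TUMOR)

    def test_three_prediction_hand_case(self):
        """confidences 0.9/0.8/0.7 scoring TP/FP/TP with 2 ground truths."""
        gts = gt_of({"a": [B(0, 0, 50, 40)], "b": [B(0, 0, 50, 40)]})
        preds = {
            "a": [B(0, 0, 50, 40, conf=0.9), B(200, 200, 50, 40, conf=0.8)],
            "b": [B(2, 0, 50, 40, conf=0.7)],
        }
        got = average_precision_50(preds, gts, ObjectClass.TUMOR)
        expected = brute_force_ap([(0.9, True), (0.8, False), (0.7, True)], n_gt=2)
        assert got == pytest.approx(expected)
        # hand arithmetic: r=0.5 at p=1, then r=1.0 at best p>= 2/3
        assert expected == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_oracle_agreement_on_small_fixtures(self, rng):
        """AP on <=5-box fixtures equals brute-force curve enumeration."""
        for trial in range(40):
            n_gt = int(rng.integers(1, 4))
            gts = gt_of({f"i{k}": [B(0, k * 100, 50, 40)] for k in range(n_gt)})
            records = []
            preds = {f"i{k}": [] for k in range(n_gt)}
            for k in range(n_gt):
                conf = float(rng.uniform(0.1, 1.0))
                if rng.random() < 0.6:  # true positive
                    preds[f"i{k}"].append(B(2, k * 100, 50, 40, conf=conf))
                    records.append((conf, True))
                if rng.random() < 0.5:  # false positive
                    fpc = float(rng.uniform(0.1, 1.0))
                    preds[f"i{k}"].append(B(400, 400, 30, 30, conf=fpc))
                    records.append((fpc, False))
            got = average_precision_50(preds, gts, ObjectClass.TUMOR)
            assert got == pytest.approx(brute_force_ap(records, n_gt) if records else 0.0)

    def test_removing_false_positive_never_decreases_ap(self):
        gts = gt_of({"a": [B(0, 0, 50, 40)], "b": [B(0, 0, 50, 40)]})
        with_fp = {
            "a": [B(0, 0, 50, 40, conf=0.9), B(300, 300, 20, 20, conf=0.95)],
            "b": [B(0, 0, 50, 40, conf=0.5)],
        }
        without_fp = {
            "a": [B(0, 0, 50, 40, conf=0.9)],
            "b": [B(0, 0, 50, 40, conf=0.5)],
        }
        assert average_precision_50(without_fp, gts, ObjectClass.TUMOR) >= \
            average_precision_50(with_fp, gts, ObjectClass.TUMOR)


class TestConfusionMetrics:
    def _result(self, tp, fp, fn, tn):
        m = MatchResult()
        for cls in ObjectClass:
            m.tp[cls], m.fp[cls], m.fn[cls], m.tn[cls] = 0, 0, 0, 0
        m.tp[ObjectClass.TUMOR], m.fp[ObjectClass.TUMOR] = tp, fp
        m.fn[ObjectClass.TUMOR], m.tn[ObjectClass.TUMOR] = fn, tn
        return m

    def test_hand_arithmetic(self):
        rep = confusion_metrics(self._result(3, 1, 1, 5))
        cm = rep.per_class[ObjectClass.TUMOR]
        assert cm.precision == pytest.approx(0.75)
        assert cm.recall == pytest.approx(0.75)
        assert cm.specificity == pytest.approx(5 / 6)
        assert cm.err == pytest.approx(0.2)

    def test_perfect_classification_mcc(self):
        cm = confusion_metrics(self._result(7, 0, 0, 7)).per_class[ObjectClass.TUMOR]
        assert cm.mcc == pytest.approx(1.0)

    def test_degenerate_counts(self):
        cm = confusion_metrics(self._result(0, 0, 0, 0)).per_class[ObjectClass.TUMOR]
        assert cm.mcc == 0.0
        assert cm.precision is None and cm.recall is None
        assert cm.specificity is None and cm.err is None

    def test_mcc_symmetry(self, rng):
        """Swapping (TP<->TN, FP<->FN) leaves MCC unchanged."""
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 30, size=4))
            a = confusion_metrics(self._result(tp, fp, fn, tn)).per_class[ObjectClass.TUMOR]
            b = confusion_metrics(self._result(tn, fn, fp, tp)).per_class[ObjectClass.TUMOR]
            assert a.mcc == pytest.approx(b.mcc)

    def test_mcc_formula_against_direct_computation(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 40, size=4))
            cm = confusion_metrics(self._result(tp, fp, fn, tn)).per_class[ObjectClass.TUMOR]
            direct = (tp * tn - fp * fn) / np.sqrt(
                float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            )
            assert cm.mcc == pytest.approx(direct)


class TestReportAssembly:
    def test_evaluate_end_to_end_report(self):
        gts = gt_of({
            "a": [B(0, 0, 50, 40), B(100, 100, 60, 30, cls=ObjectClass.SLOT)],
            "b": [B(0, 0, 50, 40)],
        })
        preds = {"a": list(gts.boxes["a"]), "b": []}
        rep = evaluate(preds, gts)
        d = rep.to_dict()
        assert d["tumor"]["precision"] == 1.0
        assert d["tumor"]["recall"] == 0.5
        assert d["cutter_slot" if "cutter_slot" in d else "slot"]["mAP50"] == 1.0
        assert "tn_convention" in d
        table = rep.format_table()
        assert "mAP50(tumor)" in table and "MCC(all)" in table


class TestPatientFolds:
    def _gts(self, n_patients, images_per_patient=3):
        boxes, patients = {}, {}
        for p in range(n_patients):
            for i in range(images_per_patient):
                key = f"p{p}_i{i}"
                boxes[key] = []
                patients[key] = f"patient{p}"
        return GroundTruthSet(boxes, patients)

    def test_balanced_folds(self):
        folds = patient_fold_split(self._gts(6), k=3, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [6, 6, 6]  # 2 patients x 3 images each

    def test_deterministic_given_seed(self):
        a = patient_fold_split(self._gts(7), k=3, seed=42)
        b = patient_fold_split(self._gts(7), k=3, seed=42)
        assert a == b
        c = patient_fold_split(self._gts(7), k=3, seed=43)
        assert a != c  # 7 patients: different shuffles almost surely differ

    def test_no_patient_straddles_folds(self, rng):
        for trial in range(10):
            n = int(rng.integers(4, 12))
            gts = self._gts(n, images_per_patient=int(rng.integers(1, 5)))
            folds = patient_fold_split(gts, k=3, seed=trial)
            for f1, f2 in itertools.combinations(folds, 2):
                assert not f1 & f2
            for fold in folds:
                pats = {gts.patients[i] for i in fold}
                for other in folds:
                    if other is not fold:
                        assert not pats & {gts.patients[i] for i in other}

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            patient_fold_split(self._gts(2), k=3)

    def test_missing_patient_id_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthSet({"a": []}, {})
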