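import math

import numpy as np
import pytest

from conftest import make_object
from trapquant.annotation import (
    Annotation,
    AnnotationLabel,
    auto_thresholds,
    export_annotated_crops,
    read_annotations,
    sample_objects,
    validate,
    write_annotations,
)
from trapquant.errors import FittingError, MissingPredictionError, SampleSizeError
from trapquant.features import FeatureVector
from trapquant.io_formats import ChannelRole, FieldOfView


def ann(oid, label, annotator="a1", dataset="ds"):
    return Annotation(object_id=oid, dataset=dataset, annotator_id=annotator, label=label)


def make_fv(pa=100.0, ar=1.0, dd=1.0, rs=1.0):
    return FeatureVector(
        protein_area=pa, dna_area=pa * ar, area_ratio=ar,
        dna_deformation=dd, dna_radius_std=rs, dna_radius_cv=0.1,
    )


class TestValidate:
    def test_perfect_classifier(self):
        anns = [ann(f"n{i}", AnnotationLabel.NET) for i in range(50)]
        anns += [ann(f"c{i}", AnnotationLabel.NEUTROPHIL) for i in range(50)]
        preds = {f"n{i}": True for i in range(50)} | {f"c{i}": False for i in range(50)}
        rep = validate(anns, preds)
        assert rep.acc == 1.0 and rep.fdr == 0.0
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (50, 0, 0, 50)

    def test_known_confusion_counts(self):
        # TP=40, FN=18, TN=42, FP=0 -> ACC = 82/100, FDR = 0
        anns, preds = [], {}
        for i in range(58):
            anns.append(ann(f"net{i}", AnnotationLabel.NET))
            preds[f"net{i}"] = i < 40
        for i in range(42):
            anns.append(ann(f"neu{i}", AnnotationLabel.NEUTROPHIL))
            preds[f"neu{i}"] = False
        rep = validate(anns, preds)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (40, 18, 0, 42)
        assert rep.acc == pytest.approx(0.82)
        assert rep.fdr == 0.0

    def test_matches_brute_force_tally_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        labels = list(AnnotationLabel)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            anns = [ann(f"o{i}", labels[rng.integers(len(labels))]) for i in range(n)]
            preds = {f"o{i}": bool(rng.random() < 0.5) for i in range(n)}
            rep = validate(anns, preds)
            tp = sum(1 for a in anns if a.label == AnnotationLabel.NET and preds[a.object_id])
            fn = sum(1 for a in anns if a.label == AnnotationLabel.NET and not preds[a.object_id])
            fp = sum(1 for a in anns if a.label == AnnotationLabel.NEUTROPHIL and preds[a.object_id])
            tn = sum(1 for a in anns if a.label == AnnotationLabel.NEUTROPHIL and not preds[a.object_id])
            assert (rep.tp, rep.fn, rep.fp, rep.tn) == (tp, fn, fp, tn)
            total = tp + fn + fp + tn
            if total:
                assert rep.acc == (tp + tn) / total
            else:
                assert rep.empty and math.isnan(rep.acc)
            assert rep.fdr == (fp / (tp + fp) if tp + fp else 0.0)
            excl = sum(
                1 for a in anns if a.label not in (AnnotationLabel.NET, AnnotationLabel.NEUTROPHIL)
            )
            assert rep.n_excluded == excl

    def test_only_unknown_labels_is_empty_report(self):
        anns = [ann(f"o{i}", AnnotationLabel.UNKNOWN) for i in range(10)]
        preds = {f"o{i}": True for i in range(10)}
        rep = validate(anns, preds)
        assert rep.empty and rep.n_excluded == 10
        assert math.isnan(rep.acc)
        assert rep.per_label_net_rate["Unknown"] == 1.0

    def test_missing_prediction_names_object(self):
        with pytest.raises(MissingPredictionError, match="o7"):
            validate([ann("o7", AnnotationLabel.NET)], {})


class TestSampling:
    pools = {"A": [f"a{i}" for i in range(120)], "B": [f"b{i}" for i in range(150)]}

    def test_full_pool_sample_is_permutation(self):
        res = sample_objects(self.pools, 270, seed=1)
        ids = sorted(f"{r.dataset}:{r.object_id}" for r in res.items)
        expected = sorted(f"{d}:{o}" for d, oids in self.pools.items() for o in oids)
        assert ids == expected

    def test_same_seed_reproduces_sample_and_order(self):
        a = sample_objects(self.pools, 50, seed=9)
        b = sample_objects(self.pools, 50, seed=9)
        assert [(r.dataset, r.object_id) for r in a.items] == [
            (r.dataset, r.object_id) for r in b.items
        ]

    def test_quota_counts_respected(self):
        res = sample_objects(self.pools, 250, seed=3, per_dataset_quota={"A": 100, "B": 150})
        counts = {"A": 0, "B": 0}
        for r in res.items:
            counts[r.dataset] += 1
        assert counts == {"A": 100, "B": 150}

    def test_oversized_request_raises(self):
        with pytest.raises(SampleSizeError):
            sample_objects(self.pools, 1000, seed=0)


class TestAutoThresholds:
    def _toy(self, net_vals, neu_vals, feature="pa"):
        feats, anns = {}, []
        for i, v in enumerate(net_vals + neu_vals):
            kw = {feature: float(v)}
            feats[f"o{i}"] = make_fv(**kw)
            label = AnnotationLabel.NET if i < len(net_vals) else AnnotationLabel.NEUTROPHIL
            anns.append(ann(f"o{i}", label))
        return anns, feats

    def test_separable_1d_threshold_in_gap(self):
        anns, feats = self._toy([5, 6, 7], [1, 2, 3])
        fit = auto_thresholds(anns, feats)
        assert fit.accuracy == 1.0
        thr = {c.feature.value: c.threshold for c in fit.criteria}
        assert 3 < thr["protein_area"] <= 5

    def test_fully_separable_classes(self):
        rng = np.random.default_rng(2)
        feats, anns = {}, []
        for i in range(30):
            is_net = i < 12
            base = 10.0 if is_net else 1.0
            feats[f"o{i}"] = make_fv(
                pa=base * 100 + rng.random(), ar=base + rng.random() * 0.1,
                dd=base + rng.random() * 0.1, rs=base + rng.random() * 0.1,
            )
            anns.append(ann(f"o{i}", AnnotationLabel.NET if is_net else AnnotationLabel.NEUTROPHIL))
        fit = auto_thresholds(anns, feats)
        assert fit.accuracy == 1.0 and fit.fdr == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_attains_exhaustive_two_feature_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = not y[0]
        f1 = rng.normal(0, 1, n) + y * 1.2
        f2 = rng.normal(0, 1, n) + y * 1.2
        feats, anns = {}, []
        for i in range(n):
            feats[f"o{i}"] = make_fv(pa=f1[i] + 10, ar=f2[i] + 10, dd=5.0, rs=5.0)
            anns.append(ann(f"o{i}", AnnotationLabel.NET if y[i] else AnnotationLabel.NEUTROPHIL))

        def cands(v):
            u = np.unique(v)
            return np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2, [u[-1] + 1]])

        best = max(
            float((((f1 + 10 >= t1) & (f2 + 10 >= t2)) == y).mean())
            for t1 in cands(f1 + 10)
            for t2 in cands(f2 + 10)
        )
        fit = auto_thresholds(anns, feats)
        assert fit.accuracy == pytest.approx(best, abs=1e-12)

    def test_never_below_best_single_feature(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            n = 25
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            vals = rng.normal(0, 1, (n, 4)) + y[:, None] * rng.uniform(0, 2, 4)
            feats = {
                f"o{i}": make_fv(pa=vals[i, 0], ar=vals[i, 1], dd=vals[i, 2], rs=vals[i, 3])
                for i in range(n)
            }
            anns = [
                ann(f"o{i}", AnnotationLabel.NET if y[i] else AnnotationLabel.NEUTROPHIL)
                for i in range(n)
            ]

            def single_best(col):
                u = np.unique(col)
                cands = np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2, [u[-1] + 1]])
                return max(float(((col >= t) == y).mean()) for t in cands)

            best_single = max(single_best(vals[:, j]) for j in range(4))
            fit = auto_thresholds(anns, feats)
            assert fit.accuracy >= best_single - 1e-12

    def test_fdr_zero_objective_enforced(self):
        rng = np.random.default_rng(8)
        n = 30
        y = np.arange(n) < 10
        vals = rng.normal(0, 1, (n, 4)) + y[:, None] * 0.8  # overlapping classes
        feats = {
            f"o{i}": make_fv(pa=vals[i, 0], ar=vals[i, 1], dd=vals[i, 2], rs=vals[i, 3])
            for i in range(n)
        }
        anns = [
            ann(f"o{i}", AnnotationLabel.NET if y[i] else AnnotationLabel.NEUTROPHIL)
            for i in range(n)
        ]
        fit = auto_thresholds(anns, feats, objective="max_accuracy_fdr0")
        assert fit.fdr == 0.0

    def test_single_class_raises(self):
        anns, feats = self._toy([5, 6], [])
        with pytest.raises(FittingError):
            auto_thresholds(anns, feats)

    def test_other_labels_ignored_in_fit(self):
        anns, feats = self._toy([5, 6, 7], [1, 2, 3])
        feats["extra"] = make_fv(pa=100)
        anns.append(ann("extra", AnnotationLabel.UNKNOWN))
        fit = auto_thresholds(anns, feats)
        assert fit.n_positive == 3 and fit.n_negative == 3


class TestAnnotationIOAndCrops:
    def test_annotation_csv_roundtrip(self, tmp_path):
        anns = [
            ann("o1", AnnotationLabel.NET),
            ann("o2", AnnotationLabel.MULTIPLE_INTACT_CELLS, annotator="a2"),
        ]
        write_annotations(anns, tmp_path / "a.csv")
        assert read_annotations(tmp_path / "a.csv") == anns

    def _setup(self):
        dna = np.full((64, 64), 7, dtype=np.uint16)
        pro = np.full((64, 64), 9, dtype=np.uint16)
        fov = FieldOfView(
            id="f", channels=[dna, pro], roles=[ChannelRole.DNA, ChannelRole.NET_PROTEIN]
        )
        m = np.zeros((64, 64), dtype=bool)
        m[1:6, 1:6] = True  # near the border
        m2 = np.zeros((64, 64), dtype=bool)
        m2[30:40, 30:40] = True
        objs = {
            "o1": make_object(m, m, object_id="o1", field_id="f"),
            "o2": make_object(m2, m2, object_id="o2", field_id="f"),
        }
        return fov, objs

    def test_export_counts_padding_and_determinism(self, tmp_path):
        import tifffile

        fov, objs = self._setup()
        anns = [
            ann("o1", AnnotationLabel.NET),
            ann("o2", AnnotationLabel.NEUTROPHIL),
            ann("o2", AnnotationLabel.NEUTROPHIL, annotator="a2"),
        ]
        manifest = export_annotated_crops(anns, objs, {"f": fov}, tmp_path / "crops", crop_radius=16)
        lines = manifest.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 rows
        crops = sorted((tmp_path / "crops").glob("*.tif"))
        assert len(crops) == 3
        border_crop = tifffile.imread(tmp_path / "crops" / "o1_a1.tif")
        assert border_crop.shape == (2, 33, 33)
        assert border_crop[0, 0, 0] == 0  # zero padding above the border
        first = manifest.read_bytes()
        export_annotated_crops(anns, objs, {"f": fov}, tmp_path / "crops", crop_radius=16)
        assert manifest.read_bytes() == first
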