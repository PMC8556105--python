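"""Two-stage cascade: detection, one-vs-rest assignment, gate semantics,
determinism, model archive."""

import numpy as np
import pytest

import metalsite as m
from metalsite.cascade import (
    LayoutMismatchError,
    CascadeModel,
    predict_cascade,
    predictions_to_records,
    train_stage1,
    train_stage2,
)
from metalsite.curation import ION_CLASSES
from metalsite.features import FeatureLayout, FeatureMatrix, WindowSample, extract_windows
from metalsite.sampling import undersample

FAST = m.rf_factory(m.RFParams(n_trees=80))


def _windows(ds, fms, binary=True):
    out = []
    for c in ds.chains:
        ws = extract_windows(fms[c.chain_id], c.label_sets, 9)
        for s in ws:
            label = (1 if s.label else 0) if binary else s.label
            out.append(WindowSample(s.chain_id, s.center, s.vector, label, s.w))
    return out


class TestStage1:
    def test_planted_signal_training_set_mcc_near_one(self, trained_cascade):
        """3σ planted windows are essentially separable: training-set MCC ≥ 0.99."""
        from sklearn.metrics import matthews_corrcoef

        ds, fms, model = trained_cascade
        ws = _windows(ds, fms)
        X = np.stack([s.vector for s in ws])
        y = np.array([s.label for s in ws])
        pred = model.stage1.predict(X)
        assert matthews_corrcoef(y, pred) >= 0.99

    def test_shuffled_labels_give_chance_mcc_held_out(self):
        from sklearn.metrics import matthews_corrcoef

        ds = m.generate_dataset(m.FixtureSpec(n_chains=12, seed=31))
        fms = ds.assemble()
        ws = _windows(ds, fms)
        rng = np.random.default_rng(0)
        labels = np.array([s.label for s in ws])
        rng.shuffle(labels)
        shuffled = [
            WindowSample(s.chain_id, s.center, s.vector, int(l), s.w)
            for s, l in zip(ws, labels)
        ]
        split = int(0.7 * len(shuffled))
        clf = train_stage1(undersample(shuffled[:split], seed=0), FAST, seed=0)
        X = np.stack([s.vector for s in shuffled[split:]])
        y = np.array([s.label for s in shuffled[split:]])
        assert abs(matthews_corrcoef(y, clf.predict(X))) < 0.1

    def test_single_class_training_rejected(self):
        ws = [WindowSample("c", i, np.zeros(5), 1, 1) for i in range(10)]
        with pytest.raises(ValueError, match="single class"):
            train_stage1(ws, FAST)

    def test_same_data_and_seed_reproduce_predictions(self, trained_cascade):
        ds, fms, model = trained_cascade
        model2 = m.train_cascade(ds.chains, fms, seed=21, factory=FAST)
        X = np.stack([s.vector for s in _windows(ds, fms)[:50]])
        np.testing.assert_array_equal(
            model.stage1.predict_proba(X), model2.stage1.predict_proba(X)
        )


class TestStage2:
    def test_disabled_class_for_degenerate_counts(self):
        rng = np.random.default_rng(0)
        samples = [
            WindowSample("c", i, rng.normal(size=6), "Zn", 1) for i in range(20)
        ] + [
            WindowSample("c", 100 + i, rng.normal(size=6) + 3, "Ca", 1)
            for i in range(20)
        ] + [WindowSample("c", 999, rng.normal(size=6), "Hg", 1)]
        with pytest.warns(UserWarning, match="Hg"):
            scorers = train_stage2(samples, FAST, seed=0)
        assert scorers["Hg"] is None
        assert scorers["Zn"] is not None and scorers["Ca"] is not None
        for cls in ("K", "Na", "Mg", "Others"):
            assert scorers[cls] is None

    def test_unlabeled_sample_rejected(self):
        samples = [WindowSample("c", 0, np.zeros(3), frozenset(), 1)]
        with pytest.raises(ValueError, match="ion class"):
            train_stage2(samples, FAST)

    def test_symmetric_classes_are_indistinguishable(self):
        """Two classes with identical feature distributions get statistically
        indistinguishable one-vs-rest scores (paired sign test)."""
        from scipy.stats import binomtest

        rng = np.random.default_rng(5)
        samples = []
        for i in range(60):
            cls = "Zn" if i % 2 == 0 else "Ca"
            samples.append(WindowSample("c", i, rng.normal(size=8), cls, 1))
        scorers = train_stage2(samples, FAST, seed=0)
        X = rng.normal(size=(200, 8))
        a = scorers["Zn"].predict_proba(X)[:, 1]
        b = scorers["Ca"].predict_proba(X)[:, 1]
        diff = a - b
        n_pos = int((diff > 0).sum())
        n = int((diff != 0).sum())
        assert binomtest(n_pos, n, 0.5).pvalue > 0.01


class _Const:
    """Deterministic stand-in scorer returning a fixed probability."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([1 - np.full(len(X), self.p),
                                np.full(len(X), self.p)])


def _const_model(stage1_p, class_ps, w=1, d=4):
    layout = FeatureLayout(("PSSM",), (d,), w, "zero")
    stage2 = {cls: _Const(class_ps.get(cls)) if cls in class_ps else None
              for cls in ION_CLASSES}
    return CascadeModel(_Const(stage1_p), stage2, layout)


def _fm(rng, L=3, d=4):
    return FeatureMatrix("c", rng.normal(size=(L, d)),
                         [f"PSSM_{i}" for i in range(d)], ("PSSM",))


class TestGate:
    def test_below_threshold_gets_no_class_and_no_probs(self, rng):
        model = _const_model(0.3, {"Zn": 0.9})
        (p, *_) = predict_cascade(model, [_fm(rng)])
        assert p.stage1_label == 0
        assert p.assigned_class is None and p.class_probs is None
        rec = predictions_to_records([p])[0]
        assert rec["prob_Zn"] is None and rec["assigned_class"] == ""

    def test_argmax_assignment(self, rng):
        probs = {c: 0.1 for c in ION_CLASSES}
        probs["Hg"] = 0.9
        model = _const_model(0.8, probs)
        (p, *_) = predict_cascade(model, [_fm(rng)])
        assert p.stage1_label == 1 and p.assigned_class == "Hg"

    def test_exact_tie_goes_to_earlier_class_in_fixed_order(self, rng):
        model = _const_model(0.8, {"Na": 0.7, "Ca": 0.7, "Hg": 0.2})
        (p, *_) = predict_cascade(model, [_fm(rng)])
        assert p.assigned_class == "Ca"  # Ca precedes Na in (K, Ca, Na, …)

    def test_disabled_class_never_assigned(self, rng):
        model = _const_model(0.8, {"Zn": 0.1})  # only Zn enabled
        preds = predict_cascade(model, [_fm(rng, L=5)])
        assert all(p.assigned_class == "Zn" for p in preds)

    def test_raising_threshold_never_adds_classed_residues(self, trained_cascade):
        ds, fms, model = trained_cascade
        fms_list = [fms[c] for c in list(fms)[:4]]
        counts = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            preds = predict_cascade(model, fms_list, threshold=thr)
            counts.append(sum(p.assigned_class is not None for p in preds))
        assert counts == sorted(counts, reverse=True)

    def test_gate_consistency_no_class_without_positive_call(self, trained_cascade):
        ds, fms, model = trained_cascade
        preds = predict_cascade(model, list(fms.values()))
        assert all(
            (p.assigned_class is None) == (p.stage1_label == 0) for p in preds
        )


class TestLayoutGuard:
    def test_wrong_width_refused_with_diff(self, rng, trained_cascade):
        _, _, model = trained_cascade
        bad = FeatureMatrix("c", rng.normal(size=(5, 20)),
                            [f"PSSM_{i}" for i in range(20)], ("PSSM",))
        with pytest.raises(LayoutMismatchError, match="channels"):
            predict_cascade(model, [bad])


class TestArchive:
    def test_save_load_round_trip(self, tmp_path, trained_cascade):
        ds, fms, model = trained_cascade
        m.save_model(model, tmp_path / "model")
        back = m.load_model(tmp_path / "model")
        assert back.layout == model.layout
        assert back.enabled_classes == model.enabled_classes
        fms_list = [fms[c] for c in list(fms)[:2]]
        a = predict_cascade(model, fms_list)
        b = predict_cascade(back, fms_list)
        assert [(p.chain_id, p.position, p.stage1_prob, p.assigned_class)
                for p in a] == \
               [(p.chain_id, p.position, p.stage1_prob, p.assigned_class)
                for p in b]
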