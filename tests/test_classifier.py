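import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import rsict2 as r
from rsict2 import classifier as clf
from rsict2.volumes import CompartmentMaps, PatientMaps, RsirsMap, T2Maps


def make_patient_maps(
    pid, label, rsirs, t2_c=None, lesion=None, prostate=None, grade_group=None
):
    """Hand-built PatientMaps on a small grid for unit tests."""
    grid = rsirs.shape
    prostate = np.ones(grid, bool) if prostate is None else prostate
    t2 = np.full(grid + (4,), 100.0) if t2_c is None else t2_c
    c = np.zeros(grid + (4,))
    c[..., 0] = rsirs  # reference C1 proportional to rsirs
    cm = CompartmentMaps(
        c=c, te=76.0, residual=np.zeros(grid), b_values=np.array([0.0])
    )
    masks = {"prostate": prostate}
    if lesion is not None:
        masks["lesion"] = lesion
    return PatientMaps(
        patient_id=pid,
        label=label,
        grade_group=grade_group if grade_group is not None else (2 if label else 0),
        masks=masks,
        compartments={76.0: cm},
        t2=T2Maps(
            t2=t2, valid=np.isfinite(t2), te_pair=(76.0, 90.0), window=(1.0, 2000.0)
        ),
        rsirs=RsirsMap(rsirs=rsirs, reference_value=1.0, reference_te=76.0),
    )


def separable_training_frame(rng, n_pat=12, rows_per=60, margin=1.0):
    frames = []
    for i in range(n_pat):
        label = i % 2
        rsirs = rng.normal(label * 2 * margin, 0.3, rows_per)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": f"p{i}",
                    "rsirs": rsirs,
                    "t2_c1": rng.normal(60, 5, rows_per),
                    "t2_c2": rng.normal(120, 10, rows_per),
                    "t2_c3": rng.normal(350, 20, rows_per),
                    "label": label,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestBuildTrainingSet:
    def test_labeling_rules(self):
        grid = (6, 6, 2)
        lesion = np.zeros(grid, bool)
        lesion[:2, :2, 0] = True
        pos = make_patient_maps("pos", True, np.random.rand(*grid), lesion=lesion)
        neg = make_patient_maps("neg", False, np.random.rand(*grid))
        table, dropped = clf.build_training_set([pos, neg])
        assert dropped == 0
        assert (table[table.label == 1].patient_id == "pos").all()
        assert len(table[table.label == 1]) == lesion.sum()
        # the csPCa patient's non-lesion voxels never appear
        assert len(table[table.patient_id == "pos"]) == lesion.sum()
        assert len(table[table.label == 0]) == np.prod(grid)

    def test_invalid_features_dropped_and_counted(self):
        grid = (4, 4, 1)
        t2 = np.full(grid + (4,), 100.0)
        t2[0, 0, 0, 0] = np.nan
        neg = make_patient_maps("neg", False, np.random.rand(*grid), t2_c=t2)
        table, dropped = clf.build_training_set([neg])
        assert dropped == 1
        assert len(table) == np.prod(grid) - 1

    def test_cspca_without_lesion_mask_rejected(self):
        pm = make_patient_maps("sick", True, np.random.rand(4, 4, 1))
        with pytest.raises(ValueError, match="sick"):
            clf.build_training_set([pm])

    def test_all_invalid_rejected(self):
        grid = (3, 3, 1)
        t2 = np.full(grid + (4,), np.nan)
        pm = make_patient_maps("neg", False, np.random.rand(*grid), t2_c=t2)
        with pytest.raises(ValueError):
            clf.build_training_set([pm])


class TestTrainLRM:
    def test_uninformative_features_give_null_model(self):
        rng = np.random.default_rng(0)
        df = separable_training_frame(rng, margin=0.0)
        df["rsirs"] = rng.normal(0, 1, len(df))
        model = clf.train_lrm(df)
        auc = clf.roc_auc(model.predict_proba(df), df.label.to_numpy())
        assert abs(auc - 0.5) < 0.05
        assert abs(model.coefficients["rsirs"]) < 0.2

    def test_separable_labels_recovered(self):
        df = separable_training_frame(np.random.default_rng(1), margin=1.5)
        model = clf.train_lrm(df)
        auc = clf.roc_auc(model.predict_proba(df), df.label.to_numpy())
        assert auc > 0.999

    def test_row_duplication_leaves_coefficients(self):
        df = separable_training_frame(np.random.default_rng(2), margin=0.3)
        a = clf.train_lrm(df)
        b = clf.train_lrm(pd.concat([df, df], ignore_index=True))
        for k in a.coefficients:
            assert a.coefficients[k] == pytest.approx(b.coefficients[k], abs=1e-3)

    def test_single_class_rejected(self):
        df = separable_training_frame(np.random.default_rng(3))
        with pytest.raises(ValueError):
            clf.train_lrm(df[df.label == 0])

    def test_winsor_bounds_stored_and_applied(self):
        df = separable_training_frame(np.random.default_rng(4), margin=0.3)
        model = clf.train_lrm(df)
        assert "t2_c1" in model.feature_bounds
        assert "rsirs" not in model.feature_bounds
        lo, hi = model.feature_bounds["t2_c1"]
        extreme = df.head(2).copy()
        extreme["t2_c1"] = [lo - 1e6, hi + 1e6]
        capped = df.head(2).copy()
        capped["t2_c1"] = [lo, hi]
        assert np.allclose(
            model.predict_proba(extreme), model.predict_proba(capped)
        )


class TestCrossValidation:
    def test_same_seed_reproducible(self):
        df = separable_training_frame(np.random.default_rng(5), margin=0.4)
        a = clf.cv_voxel_auc(df, k=4, seed=3, n_boot=200)
        b = clf.cv_voxel_auc(df, k=4, seed=3, n_boot=200)
        assert a.auc == b.auc
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_separable_cohort_perfect_auc(self):
        df = separable_training_frame(np.random.default_rng(6), margin=2.0)
        res = clf.cv_voxel_auc(df, k=4, seed=0, n_boot=200)
        assert res.auc == pytest.approx(1.0, abs=1e-9)

    def test_label_independent_features_near_chance(self):
        # features carry no label information at all: pooled out-of-fold
        # AUC over >5000 voxels sits near 0.5
        rng = np.random.default_rng(7)
        df = separable_training_frame(rng, n_pat=20, rows_per=300, margin=0.0)
        res = clf.cv_voxel_auc(df, k=5, seed=1, n_boot=100)
        assert abs(res.auc - 0.5) < 0.05

    def test_too_many_folds_rejected(self):
        df = separable_training_frame(np.random.default_rng(8), n_pat=4)
        with pytest.raises(ValueError, match="folds"):
            clf.cv_voxel_auc(df, k=10, seed=0)

    def test_patient_voxels_never_split_across_folds(self):
        from sklearn.model_selection import StratifiedGroupKFold

        df = separable_training_frame(np.random.default_rng(9), n_pat=10)
        groups = df["patient_id"].to_numpy()
        folds = np.empty(len(df), int)
        for f, (_, test_idx) in enumerate(
            StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=0).split(df, df.label, groups=groups)
        ):
            folds[test_idx] = f
        for pid in df.patient_id.unique():
            assert len(np.unique(folds[groups == pid])) == 1


class TestPatientScores:
    def test_max_probability_picks_hot_voxel(self):
        grid = (5, 5, 1)
        rsirs = np.full(grid, 0.1)
        rsirs[2, 2, 0] = 0.9
        pm = make_patient_maps("a", False, rsirs)
        model = clf.FittedLRM(
            intercept=-2.0,
            coefficients={"rsirs": 5.0, "t2_c1": 0.0, "t2_c2": 0.0, "t2_c3": 0.0},
            n_rows=1,
        )
        scores = clf.patient_scores([pm], model)
        expected = 1 / (1 + np.exp(-(-2.0 + 5.0 * 0.9)))
        assert scores.max_probability.iloc[0] == pytest.approx(expected)
        assert scores.max_rsirs.iloc[0] == pytest.approx(0.9)

    def test_zero_t2_weights_rank_like_rsirs(self, small_cohort_maps):
        pms, _ = small_cohort_maps
        model = clf.FittedLRM(
            intercept=0.0,
            coefficients={"rsirs": 3.0, "t2_c1": 0.0, "t2_c2": 0.0, "t2_c3": 0.0},
            n_rows=1,
        )
        scores = clf.patient_scores(pms, model)
        assert (
            scores.max_probability.rank() == scores.max_rsirs.rank()
        ).all()

    def test_empty_prostate_mask_rejected(self):
        pm = make_patient_maps(
            "a", False, np.random.rand(3, 3, 1), prostate=np.zeros((3, 3, 1), bool)
        )
        model = clf.FittedLRM(
            intercept=0.0,
            coefficients={"rsirs": 1.0, "t2_c1": 0.0, "t2_c2": 0.0, "t2_c3": 0.0},
            n_rows=1,
        )
        with pytest.raises(ValueError, match="prostate"):
            clf.patient_scores([pm], model)


class TestBootstrapAuc:
    def test_perfect_ranking(self):
        scores = np.arange(20, dtype=float)
        labels = scores >= 10
        res = clf.bootstrap_auc(scores, labels, n_boot=500, seed=0)
        assert res.auc == 1.0
        assert (res.ci_lower, res.ci_upper) == (1.0, 1.0)

    def test_null_ci_covers_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200).astype(bool)
        res = clf.bootstrap_auc(scores, labels, n_boot=2000, seed=1)
        assert res.ci_lower < 0.5 < res.ci_upper

    def test_same_seed_identical(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50).astype(bool)
        a = clf.bootstrap_auc(scores, labels, n_boot=500, seed=7)
        b = clf.bootstrap_auc(scores, labels, n_boot=500, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_small_n_boot_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            clf.bootstrap_auc(
                np.arange(10.0), np.arange(10) >= 5, n_boot=50, seed=0
            )
        assert "n_boot" in caplog.text

    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_auc_invariant_under_monotone_transforms(self, kind):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80).astype(bool)
        f = {"exp": np.exp, "cube": lambda x: x**3, "affine": lambda x: 2 * x + 5}[kind]
        assert clf.roc_auc(scores, labels) == pytest.approx(
            clf.roc_auc(f(scores), labels)
        )


class TestCompareAucs:
    def _result(self, samples):
        s = np.asarray(samples, float)
        return clf.AUCResult(
            auc=float(s.mean()),
            ci_lower=float(np.clip(s.min(), 0, 1)),
            ci_upper=float(np.clip(s.max(), 0, 1)),
            n_boot=len(s),
            samples=s,
        )

    def test_distribution_vs_itself_not_significant(self):
        s = np.random.default_rng(13).uniform(0.6, 0.9, 1000)
        res = clf.compare_aucs(self._result(s), self._result(s.copy()))
        assert res.p > 0.9 and not res.significant

    def test_degenerate_equal_distributions(self):
        res = clf.compare_aucs(self._result([0.8] * 100), self._result([0.8] * 100))
        assert res.p == 1.0 and not res.significant

    def test_missing_samples_rejected(self):
        a = self._result([0.7] * 100)
        b = clf.AUCResult(auc=0.8, ci_lower=0.7, ci_upper=0.9, n_boot=100, samples=None)
        with pytest.raises(ValueError):
            clf.compare_aucs(a, b)
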