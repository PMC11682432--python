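"""Voxel-level logistic-regression csPCa model and AUC evaluation.

The model estimates the probability that a voxel contains clinically
significant prostate cancer from RSIrs plus the compartmental T2 values of
C1, C2 and C3.  Training follows the lesion-contour labeling rules: in
csPCa patients only lesion voxels enter (positive) and all other voxels of
those patients are excluded; in non-csPCa patients every in-prostate voxel
enters (negative).

Evaluation: ten-fold cross-validation grouped by patient for voxel-level
AUC, patient-level AUCs of the maximum in-prostate model probability,
maximum RSIrs and maximum C1, percentile confidence intervals from 10,000
bootstrap resamples of patients, and AUC-vs-AUC comparison by a two-sample
t-test on the bootstrap distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold

from .stats import ALPHA, ComparisonResult, two_sample_test
from .volumes import PatientMaps

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "FittedLRM",
    "AUCResult",
    "build_training_set",
    "train_lrm",
    "cv_voxel_auc",
    "patient_scores",
    "bootstrap_auc",
    "compare_aucs",
    "roc_auc",
]

#: Predictors, in column order: RSIrs and the compartmental T2 of C1..C3
#: (the compartments with voxel-level T2 differences between lesion and
#: non-lesion tissue).
FEATURES = ("rsirs", "t2_c1", "t2_c2", "t2_c3")


def build_training_set(
    patients: list[PatientMaps],
) -> tuple[pd.DataFrame, int]:
    """Assemble the voxel-level training table.

    Returns ``(table, n_dropped)`` where ``n_dropped`` counts in-scope
    voxels discarded because a feature was invalid (NaN).  Raises if a
    csPCa patient lacks a lesion mask.
    """
    frames = []
    n_dropped = 0
    for pm in patients:
        prostate = pm.mask("prostate")
        if prostate is None or not prostate.any():
            raise ValueError(f"patient {pm.patient_id}: empty or missing prostate mask")
        if pm.label:
            lesion = pm.mask("lesion")
            if lesion is None or not lesion.any():
                raise ValueError(
                    f"csPCa patient {pm.patient_id} has no lesion mask"
                )
            sel = lesion
            label = 1
        else:
            sel = prostate
            label = 0
        cols = {
            "rsirs": pm.rsirs.rsirs[sel],
            "t2_c1": pm.t2.compartment(1)[sel],
            "t2_c2": pm.t2.compartment(2)[sel],
            "t2_c3": pm.t2.compartment(3)[sel],
        }
        df = pd.DataFrame(cols)
        keep = np.isfinite(df.to_numpy()).all(axis=1)
        n_dropped += int((~keep).sum())
        df = df[keep]
        df.insert(0, "patient_id", pm.patient_id)
        df["label"] = label
        frames.append(df)
    if not frames:
        raise ValueError("no patients supplied")
    table = pd.concat(frames, ignore_index=True)
    if len(table) == 0:
        raise ValueError("all candidate voxels had invalid features")
    if n_dropped:
        logger.info("dropped %d voxels with invalid features", n_dropped)
    return table, n_dropped


@dataclass
class FittedLRM:
    """Unpenalized logistic model (a vanishing ridge is kept purely as a
    numerical guard against separation).

    ``feature_bounds`` are the winsorization limits learned from the
    training set (0.5th/99.5th percentile per feature by default).  The
    two-point T2 estimator has heavy noise tails — a near-equal pair of C
    values yields a T2 near the censoring cap — and without clipping a
    single such voxel can dominate a patient's maximum probability.  The
    bounds are stored with the model and applied identically at training
    and prediction time.
    """

    intercept: float
    coefficients: dict[str, float]
    n_rows: int
    seed: int | None = None
    feature_bounds: dict[str, tuple[float, float]] | None = None

    def _clip(self, name: str, values: np.ndarray) -> np.ndarray:
        if self.feature_bounds and name in self.feature_bounds:
            lo, hi = self.feature_bounds[name]
            return np.clip(values, lo, hi)
        return values

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        z = np.full(len(table), self.intercept)
        for name, coef in self.coefficients.items():
            z = z + coef * self._clip(name, table[name].to_numpy(dtype=float))
        return z

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return _expit(self.linear_predictor(table))

    def predict_volume(self, pm: PatientMaps, impute: bool = True) -> np.ndarray:
        """Voxelwise probability map.

        T2 features are invalid (NaN) in some voxels; by default those are
        imputed with the patient's median valid in-prostate value so the
        probability map covers the same support as the RSIrs map (as a
        deployed probability map would).  With ``impute=False`` such voxels
        stay NaN.
        """
        grid = pm.rsirs.rsirs.shape
        feats = np.stack(
            [pm.rsirs.rsirs]
            + [pm.t2.compartment(i) for i in (1, 2, 3)],
            axis=-1,
        )
        if impute:
            prostate = pm.mask("prostate")
            sel = prostate if prostate is not None else np.ones(grid, dtype=bool)
            for k in range(1, feats.shape[-1]):
                plane = feats[..., k]
                bad = ~np.isfinite(plane)
                if bad.any():
                    valid = plane[sel & ~bad]
                    fill = float(np.median(valid)) if valid.size else 0.0
                    plane[bad] = fill
        for k, name in enumerate(FEATURES):
            feats[..., k] = self._clip(name, feats[..., k])
        z = self.intercept + feats @ np.array(
            [self.coefficients[f] for f in FEATURES]
        )
        out = np.full(grid, np.nan)
        ok = np.isfinite(feats).all(axis=-1)
        out[ok] = _expit(z[ok])
        return out

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "n_rows": self.n_rows,
            "seed": self.seed,
            "feature_bounds": self.feature_bounds,
        }


def _expit(z: np.ndarray) -> np.ndarray:
    return scipy.special.expit(z)


def train_lrm(
    training_set: pd.DataFrame,
    seed: int | None = None,
    standardize: bool = False,
    winsor_quantiles: tuple[float, float] | None = (0.005, 0.995),
) -> FittedLRM:
    """Maximum-likelihood logistic fit of csPCa probability per voxel.

    Deterministic given the data.  Perfect separation is tolerated (the
    tiny ridge keeps the optimum finite) but logged.  ``standardize``
    z-scores the features first; off by default so coefficients stay in
    raw units.  ``winsor_quantiles`` clips each feature to the given
    training-set quantiles (stored on the model and re-applied at
    prediction); pass ``None`` to disable.
    """
    y = training_set["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both labels")
    X = training_set.loc[:, list(FEATURES)].to_numpy(dtype=float)
    bounds: dict[str, tuple[float, float]] | None = None
    if winsor_quantiles is not None:
        # only the T2 features are clipped: their two-point estimates have
        # heavy noise tails, while RSIrs is well-behaved and must keep its
        # full resolution (clipping it would saturate high-scoring voxels)
        qlo, qhi = winsor_quantiles
        bounds = {}
        for k, f in enumerate(FEATURES):
            if f == "rsirs":
                continue
            lo = float(np.quantile(X[:, k], qlo))
            hi = float(np.quantile(X[:, k], qhi))
            X[:, k] = np.clip(X[:, k], lo, hi)
            bounds[f] = (lo, hi)
    scale = np.ones(X.shape[1])
    center = np.zeros(X.shape[1])
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - center) / scale
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    proba = clf.predict_proba(X)[:, 1]
    if np.all((proba > 0.999) == (y == 1)) and np.all((proba < 0.001) == (y == 0)):
        logger.warning("training data appear perfectly separated; fit is guarded")
    coefs = clf.coef_[0] / scale
    intercept = float(clf.intercept_[0] - np.sum(clf.coef_[0] * center / scale))
    return FittedLRM(
        intercept=intercept,
        coefficients={f: float(c) for f, c in zip(FEATURES, coefs)},
        n_rows=len(training_set),
        seed=seed,
        feature_bounds=bounds,
    )


@dataclass
class AUCResult:
    """Point AUC with a bootstrap percentile 95% CI."""

    auc: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    samples: np.ndarray = field(repr=False, default=None)
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ci_lower <= self.ci_upper <= 1:
            raise ValueError("CI bounds must satisfy 0 <= lower <= upper <= 1")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (equivalent to the area under the ROC curve)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _auc_rows(scores_2d: np.ndarray, labels_2d: np.ndarray) -> np.ndarray:
    """Row-wise AUC for bootstrap matrices (rows with one class -> NaN)."""
    ranks = scipy.stats.rankdata(scores_2d, axis=1)
    n_pos = labels_2d.sum(axis=1)
    n_neg = labels_2d.shape[1] - n_pos
    pos_rank_sum = np.where(labels_2d, ranks, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        auc = (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auc[(n_pos == 0) | (n_neg == 0)] = np.nan
    return auc


def bootstrap_auc(
    scores,
    labels,
    n_boot: int = 10_000,
    seed: int = 0,
) -> AUCResult:
    """Percentile bootstrap CI for the AUC, resampling subjects.

    Resamples containing a single class are redrawn (their count is
    recorded on the result).  The bootstrap AUC samples are kept so that
    two results can be compared with :func:`compare_aucs`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; CI will be unstable", n_boot)
    point = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    n = scores.size
    idx = rng.integers(0, n, size=(n_boot, n))
    auc = _auc_rows(scores[idx], labels[idx])
    n_redrawn = 0
    bad = np.flatnonzero(~np.isfinite(auc))
    while bad.size:
        n_redrawn += bad.size
        idx_new = rng.integers(0, n, size=(bad.size, n))
        auc[bad] = _auc_rows(scores[idx_new], labels[idx_new])
        bad = np.flatnonzero(~np.isfinite(auc))
    lo, hi = np.percentile(auc, [2.5, 97.5])
    if n_redrawn:
        logger.info("redrew %d single-class bootstrap resamples", n_redrawn)
    return AUCResult(
        auc=point,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        samples=auc,
        n_redrawn=n_redrawn,
    )


def cv_voxel_auc(
    training_set: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_boot: int = 10_000,
) -> AUCResult:
    """Voxel-level AUC under k-fold cross-validation grouped by patient.

    Folds partition patients (never voxels), out-of-fold probabilities are
    pooled, and the CI bootstraps patients (all of a patient's voxels enter
    or leave a resample together).
    """
    groups = training_set["patient_id"].to_numpy()
    unique_patients = pd.unique(groups)
    if k > len(unique_patients):
        raise ValueError(
            f"k={k} folds but only {len(unique_patients)} patients contribute rows"
        )
    y = training_set["label"].to_numpy(dtype=int)
    oof = np.full(len(training_set), np.nan)
    # folds are stratified by class so every training split sees the same
    # csPCa prevalence; with patient-grouped folds an unstratified split
    # would shift each fold's intercept with its prevalence and bias the
    # pooled out-of-fold AUC
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(training_set, y, groups):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold contains a single class; use fewer folds")
        model = train_lrm(training_set.iloc[train_idx], seed=seed)
        oof[test_idx] = model.predict_proba(training_set.iloc[test_idx])
    point = roc_auc(oof, y)

    # patient-level bootstrap of the pooled out-of-fold AUC
    rng = np.random.default_rng(seed)
    by_patient = {
        pid: (oof[groups == pid], y[groups == pid]) for pid in unique_patients
    }
    samples = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            pick = rng.choice(unique_patients, size=len(unique_patients), replace=True)
            ys = np.concatenate([by_patient[p][1] for p in pick])
            if 0 < ys.sum() < ys.size:
                break
            n_redrawn += 1
        ss = np.concatenate([by_patient[p][0] for p in pick])
        samples[b] = roc_auc(ss, ys)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return AUCResult(
        auc=point,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        samples=samples,
        n_redrawn=n_redrawn,
    )


def patient_scores(
    patients: list[PatientMaps],
    model: FittedLRM,
) -> pd.DataFrame:
    """Patient-level predictors: maxima over valid in-prostate voxels of the
    model probability, RSIrs, and C1."""
    rows = []
    for pm in patients:
        prostate = pm.mask("prostate")
        if prostate is None or not prostate.any():
            raise ValueError(f"patient {pm.patient_id}: empty prostate mask")
        prob = model.predict_volume(pm)[prostate]
        rsirs = pm.rsirs.rsirs[prostate]
        c1 = pm.reference_c1[prostate]
        rows.append(
            {
                "patient_id": pm.patient_id,
                "label": int(pm.label),
                "max_probability": float(np.nanmax(prob)),
                "max_rsirs": float(np.nanmax(rsirs)),
                "max_c1": float(np.nanmax(c1)),
            }
        )
    return pd.DataFrame(rows)


def compare_aucs(
    result_a: AUCResult,
    result_b: AUCResult,
    name_a: str = "A",
    name_b: str = "B",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Two-sample t-test on the two bootstrap AUC distributions."""
    if result_a.samples is None or result_b.samples is None:
        raise ValueError("both AUC results must carry bootstrap samples")
    return two_sample_test(
        result_a.samples, result_b.samples, group_a=name_a, group_b=name_b, alpha=alpha
    )
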