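"""Episignature classification with a nu-parameterized linear SVM.

The classifier is trained on beta values over the signature probes with a
linear kernel; ``nu`` (an upper bound on the margin-error fraction and
lower bound on the support-vector fraction) is chosen by stratified
5-fold cross-validation over a grid, after holding out a stratified test
split (25% by default).  Decision margins are mapped to [0, 1] scores by
a Platt-style sigmoid fit on out-of-fold margins, and scores are called
in three bands:

* score < 0.25          -> ``control``
* 0.25 <= score <= 0.5  -> ``inconclusive``
* score > 0.5           -> ``pathogenic``
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import NuSVC
from sklearn.utils.validation import check_is_fitted

DEFAULT_NU_GRID = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)

BAND_CONTROL = "control"
BAND_INCONCLUSIVE = "inconclusive"
BAND_PATHOGENIC = "pathogenic"


@dataclass(frozen=True)
class BandThresholds:
    """Score cutpoints for the three-band call rule."""

    control_below: float = 0.25
    pathogenic_above: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.control_below < self.pathogenic_above < 1:
            raise ValueError("require 0 < control_below < pathogenic_above < 1")


@dataclass(frozen=True)
class TrainConfig:
    test_fraction: float = 0.25
    cv_folds: int = 5
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not all(0 < nu < 1 for nu in self.nu_grid):
            raise ValueError("every nu must be in (0, 1)")


def assign_band(score: float, thresholds: BandThresholds | None = None) -> str:
    """Map a calibrated [0, 1] score to control/inconclusive/pathogenic.

    Both boundary scores (0.25 and 0.5 at defaults) fall in the
    inconclusive band.
    """
    thresholds = thresholds or BandThresholds()
    if not 0 <= score <= 1:
        raise ValueError(f"score {score!r} outside [0, 1]")
    if score < thresholds.control_below:
        return BAND_CONTROL
    if score > thresholds.pathogenic_above:
        return BAND_PATHOGENIC
    return BAND_INCONCLUSIVE


def split_train_test(sample_ids, labels, cfg: TrainConfig | None = None):
    """Deterministic stratified train/test split of sample ids."""
    cfg = cfg or TrainConfig()
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        starving = classes[counts < 2]
        raise ValueError(f"class {starving[0]!r} has a single sample")
    train_ids, test_ids = train_test_split(
        sample_ids, test_size=cfg.test_fraction, stratify=labels,
        random_state=cfg.seed,
    )
    return list(train_ids), list(test_ids)


def _fit_platt(margins: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid calibration: fit (A, B) in P = 1/(1+exp(A*f + B)).

    Uses Platt's smoothed targets so perfectly separated margins do not
    drive the slope to infinity; A is constrained nonpositive so the
    score is monotone nondecreasing in the margin.
    """
    margins = np.asarray(margins, dtype=float)
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * margins + b
        # log(1 + exp(z)) computed stably
        log1pexp = np.logaddexp(0.0, z)
        # -sum[t*log p + (1-t)*log(1-p)] with p = 1/(1+exp(z))
        return float(np.sum(log1pexp - (1 - t) * z))

    x0 = np.array([-1.0, math.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(None, 0.0), (None, None)])
    a, b = res.x
    return float(a), float(b)


def _sigmoid_score(margins: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(margins, dtype=float) + b
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class ClassifierModel:
    """Serializable trained model: linear weights over signature probes
    plus Platt calibration and training provenance."""

    probe_ids: list[str]
    weights: list[float]
    intercept: float
    calibration_a: float
    calibration_b: float
    nu: float
    thresholds: BandThresholds = field(default_factory=BandThresholds)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "probe_ids": self.probe_ids,
            "weights": self.weights,
            "intercept": self.intercept,
            "calibration": {"a": self.calibration_a, "b": self.calibration_b},
            "nu": self.nu,
            "thresholds": {"control_below": self.thresholds.control_below,
                           "pathogenic_above": self.thresholds.pathogenic_above},
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            probe_ids=list(d["probe_ids"]),
            weights=[float(w) for w in d["weights"]],
            intercept=float(d["intercept"]),
            calibration_a=float(d["calibration"]["a"]),
            calibration_b=float(d["calibration"]["b"]),
            nu=float(d["nu"]),
            thresholds=BandThresholds(**d.get("thresholds", {})),
            provenance=d.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # -- scoring ---------------------------------------------------------

    def margins(self, beta: pd.DataFrame) -> pd.Series:
        """Decision margins for samples (columns) of a probes x samples matrix."""
        missing = [p for p in self.probe_ids if p not in beta.index]
        if missing:
            raise ValueError(f"matrix lacks signature probes: {missing[:5]}")
        x = beta.loc[self.probe_ids].to_numpy(dtype=float)  # probes x samples
        if np.isnan(x).any():
            bad = beta.columns[np.isnan(x).any(axis=0)]
            raise ValueError(
                f"samples with missing values on signature probes: "
                f"{list(bad[:5])}; impute before scoring"
            )
        w = np.asarray(self.weights)
        return pd.Series(x.T @ w + self.intercept, index=beta.columns)

    def score_samples(self, beta: pd.DataFrame) -> pd.Series:
        """Calibrated [0, 1] scores, monotone in the decision margin."""
        m = self.margins(beta)
        return pd.Series(_sigmoid_score(m.to_numpy(), self.calibration_a,
                                        self.calibration_b), index=m.index)

    def classification_report(self, beta: pd.DataFrame) -> list[dict]:
        scores = self.score_samples(beta)
        return [
            {"sample_id": str(sid), "score": float(s),
             "band": assign_band(float(s), self.thresholds)}
            for sid, s in scores.items()
        ]


class EpisignatureClassifier(BaseEstimator, ClassifierMixin):
    """nu-SVM episignature classifier with internal split, CV and calibration.

    ``fit(X, y)`` takes samples x probes beta values (DataFrame or array)
    and binary labels (truthy = signature carrier).  Internally a
    stratified test split is held out, ``nu`` is picked by stratified
    k-fold cross-validation on the training portion (ties to the smallest
    nu), the SVM is refit on the whole training portion, and a Platt
    sigmoid is fit on out-of-fold margins.

    Attributes
    ----------
    nu_ : chosen nu
    coef_, intercept_ : linear decision function
    cv_results_ : mean CV accuracy per candidate nu
    test_accuracy_ : accuracy on the held-out test split
    model_ : ClassifierModel (serializable form)
    """

    def __init__(self, nu_grid=DEFAULT_NU_GRID, cv_folds: int = 5,
                 test_fraction: float = 0.25, seed: int = 0):
        self.nu_grid = nu_grid
        self.cv_folds = cv_folds
        self.test_fraction = test_fraction
        self.seed = seed

    def fit(self, X, y):
        cfg = TrainConfig(test_fraction=self.test_fraction,
                          cv_folds=self.cv_folds,
                          nu_grid=tuple(self.nu_grid), seed=self.seed)
        if isinstance(X, pd.DataFrame):
            probe_ids = [str(c) for c in X.columns]
            sample_ids = [str(i) for i in X.index]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            probe_ids = [f"f{i}" for i in range(values.shape[1])]
            sample_ids = [str(i) for i in range(values.shape[0])]
        if values.size == 0:
            raise ValueError("empty feature matrix (no signature probes?)")
        y = np.asarray(y).astype(bool)
        if y.all() or not y.any():
            raise ValueError("need both positive and negative training samples")
        self.classes_ = np.array([False, True])

        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, test_size=cfg.test_fraction, stratify=y, random_state=cfg.seed
        )
        x_train, y_train = values[train_idx], y[train_idx]
        x_test, y_test = values[test_idx], y[test_idx]
        if y_train.sum() < cfg.cv_folds or (~y_train).sum() < cfg.cv_folds:
            raise ValueError(
                "too few samples in a class for "
                f"{cfg.cv_folds}-fold stratified cross-validation"
            )

        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                              random_state=cfg.seed)
        folds = list(skf.split(x_train, y_train))
        cv_results: dict[float, float] = {}
        oof_margins: dict[float, np.ndarray] = {}
        for nu in cfg.nu_grid:
            margins = np.full(len(y_train), np.nan)
            correct = 0
            total = 0
            feasible = True
            for fold_train, fold_val in folds:
                svm = NuSVC(nu=nu, kernel="linear")
                try:
                    svm.fit(x_train[fold_train], y_train[fold_train])
                except ValueError as exc:
                    if "nu" in str(exc):
                        warnings.warn(f"nu={nu} infeasible for the class balance; skipped")
                        feasible = False
                        break
                    raise
                m = svm.decision_function(x_train[fold_val])
                margins[fold_val] = m
                correct += int(((m > 0) == y_train[fold_val]).sum())
                total += len(fold_val)
            if feasible:
                cv_results[nu] = correct / total
                oof_margins[nu] = margins
        if not cv_results:
            raise ValueError("every candidate nu was infeasible")

        best_acc = max(cv_results.values())
        nu_best = min(nu for nu, acc in cv_results.items() if acc == best_acc)

        final = NuSVC(nu=nu_best, kernel="linear")
        final.fit(x_train, y_train)
        a, b = _fit_platt(oof_margins[nu_best], y_train)

        self.nu_ = nu_best
        self.cv_results_ = cv_results
        self.coef_ = final.coef_.ravel().copy()
        self.intercept_ = float(final.intercept_[0])
        test_margin = x_test @ self.coef_ + self.intercept_
        self.test_accuracy_ = float(((test_margin > 0) == y_test).mean())
        self.calibration_ = {"a": a, "b": b}
        self.model_ = ClassifierModel(
            probe_ids=probe_ids,
            weights=[float(w) for w in self.coef_],
            intercept=self.intercept_,
            calibration_a=a, calibration_b=b, nu=nu_best,
            provenance={
                "seed": cfg.seed,
                "cv_folds": cfg.cv_folds,
                "test_fraction": cfg.test_fraction,
                "cv_accuracy_per_nu": {str(k): v for k, v in cv_results.items()},
                "test_accuracy": self.test_accuracy_,
                "train_ids": [sample_ids[i] for i in train_idx],
                "test_ids": [sample_ids[i] for i in test_idx],
                "n_train": int(len(train_idx)),
                "n_test": int(len(test_idx)),
            },
        )
        return self

    def _margins(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            missing = [p for p in self.model_.probe_ids if p not in X.columns]
            if missing:
                raise ValueError(f"missing signature probes: {missing[:5]}")
            X = X.loc[:, self.model_.probe_ids]
        values = np.asarray(X, dtype=float)
        return values @ self.coef_ + self.intercept_

    def decision_function(self, X) -> np.ndarray:
        return self._margins(X)

    def predict(self, X) -> np.ndarray:
        return self._margins(X) > 0

    def predict_score(self, X) -> np.ndarray:
        """Calibrated [0, 1] scores."""
        return _sigmoid_score(self._margins(X), **{
            "a": self.calibration_["a"], "b": self.calibration_["b"]})

    def predict_band(self, X, thresholds: BandThresholds | None = None) -> list[str]:
        return [assign_band(float(s), thresholds) for s in self.predict_score(X)]


def train_classifier(
    beta_signature: pd.DataFrame,
    labels,
    cfg: TrainConfig | None = None,
) -> ClassifierModel:
    """Train from a probes x samples matrix restricted to signature probes.

    ``labels`` are per-sample (column order), truthy = carrier.
    """
    cfg = cfg or TrainConfig()
    clf = EpisignatureClassifier(
        nu_grid=cfg.nu_grid, cv_folds=cfg.cv_folds,
        test_fraction=cfg.test_fraction, seed=cfg.seed,
    )
    clf.fit(beta_signature.T, np.asarray(labels))
    return clf.model_


def score_samples(model: ClassifierModel, beta: pd.DataFrame) -> pd.Series:
    """Calibrated scores for all samples (columns) of a beta matrix."""
    return model.score_samples(beta)
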