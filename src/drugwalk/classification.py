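"""Linear classifiers on propagated profiles.

Two linear strategies separate anti-cancer from other compounds in the
genome-wide profile space:

* **Maximum Margin Criterion (MMC)** — project onto the top eigenvectors of
  the scatter difference ``Sb - Sw`` (between-class minus within-class),
  which maximises the margin ``tr(Sb) - tr(Sw)`` in the projected space
  without inverting ``Sw`` (well-posed even when features outnumber
  samples).
* **Soft-margin linear SVM** with balanced class weights, for the ~1:9
  class imbalance of approved anti-cancer vs other drugs.

Both produce calibrated probabilities — the anti-cancer likeness (ACL) —
via Platt-style logistic regression on the raw decision values.  Gene
importance is scored as the Pearson correlation between each gene's profile
level and the model's prediction outcomes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC


@dataclass
class LabeledProfileMatrix:
    """Compounds x genes matrix of propagated scores with binary labels.

    ``y``: 1 = anti-cancer (positive class), 0 = other.
    """

    X: np.ndarray
    y: np.ndarray
    compound_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


def _fit_platt(scores: np.ndarray, y: np.ndarray) -> LogisticRegression:
    lr = LogisticRegression(class_weight="balanced", max_iter=1000)
    lr.fit(np.asarray(scores, float).reshape(len(y), -1), y)
    return lr


@dataclass
class MMCModel:
    """Maximum-margin-criterion projection plus logistic calibration."""

    projection: np.ndarray          # genes x k, orthonormal columns
    eigenvalues: np.ndarray         # descending, length k
    k: int
    class_means: dict[int, np.ndarray]
    calibration: LogisticRegression

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.projection

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.calibration.predict_proba(self.decision_scores(X))[:, 1]


def scatter_matrices(
    X: np.ndarray, y: np.ndarray, class_weighting: str = "balanced"
) -> tuple[np.ndarray, np.ndarray]:
    """Between-class (Sb) and within-class (Sw) scatter matrices.

    With ``class_weighting="balanced"`` each class contributes equal total
    weight regardless of its size, compensating the 1:9 imbalance; with
    ``"prior"`` classes are weighted by their empirical frequency.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes = np.unique(y)
    if class_weighting == "balanced":
        weights = {c: 1.0 / len(classes) for c in classes}
    elif class_weighting == "prior":
        weights = {c: float((y == c).mean()) for c in classes}
    else:
        raise ValueError(f"unknown class_weighting {class_weighting!r}")

    means = {c: X[y == c].mean(axis=0) for c in classes}
    overall = sum(weights[c] * means[c] for c in classes)
    d = X.shape[1]
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for c in classes:
        diff = means[c] - overall
        Sb += weights[c] * np.outer(diff, diff)
        centred = X[y == c] - means[c]
        Sw += weights[c] * (centred.T @ centred) / max(len(centred), 1)
    return Sb, Sw


def fit_mmc(
    data: LabeledProfileMatrix,
    k: int = 1,
    class_weighting: str = "balanced",
    calibration_scores: np.ndarray | None = None,
    calibration_labels: np.ndarray | None = None,
) -> MMCModel:
    """Fit the MMC projection and its probability calibration.

    The projection is the top-``k`` eigenvectors of ``Sb - Sw`` (symmetric,
    so the eigenbasis is orthonormal).  Calibration is logistic regression
    with balanced weights on projected decision scores — out-of-fold scores
    when supplied, else the training scores (Platt-style).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X, y = data.X, data.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("fit_mmc requires both classes present")
    if min(int((y == c).sum()) for c in classes) < 2:
        raise ValueError("fit_mmc requires >= 2 samples per class")

    Sb, Sw = scatter_matrices(X, y, class_weighting)
    eigvals, eigvecs = np.linalg.eigh(Sb - Sw)  # ascending
    order = np.argsort(eigvals)[::-1][:k]
    projection = eigvecs[:, order]
    eigenvalues = eigvals[order]

    # orient the leading axis so the positive class projects higher (sign of
    # an eigenvector is arbitrary; fixing it makes models reproducible)
    means = {c: X[y == c].mean(axis=0) for c in classes}
    direction = means[1] - means[0]
    for j in range(projection.shape[1]):
        if projection[:, j] @ direction < 0:
            projection[:, j] = -projection[:, j]

    scores = X @ projection
    if calibration_scores is not None:
        cal = _fit_platt(calibration_scores, calibration_labels)
    else:
        cal = _fit_platt(scores, y)
    return MMCModel(
        projection=projection, eigenvalues=eigenvalues, k=k,
        class_means={int(c): means[c] for c in classes}, calibration=cal,
    )


@dataclass
class TrainedClassifier:
    """A fitted linear model exposing calibrated ACL probabilities."""

    kind: Literal["linear_svm", "mmc"]
    model: object                    # LinearSVC or MMCModel
    calibration: LogisticRegression | None
    hyperparameters: dict
    n_features: int

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"profile dimension {X.shape[1]} != model dimension {self.n_features}")
        if self.kind == "linear_svm":
            return self.model.decision_function(X)
        return self.model.decision_scores(X)

    def predict_acl(self, X: np.ndarray) -> np.ndarray:
        """Calibrated anti-cancer-likeness probability in [0, 1]."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"profile dimension {X.shape[1]} != model dimension {self.n_features}")
        if self.kind == "mmc":
            return self.model.predict_proba(X)
        scores = self.model.decision_function(X)
        return self.calibration.predict_proba(scores.reshape(-1, 1))[:, 1]

    def to_json(self) -> dict:
        """Portable description of the trained model (weights + calibration)."""
        out = {"kind": self.kind, "hyperparameters": self.hyperparameters, "n_features": self.n_features}
        if self.kind == "linear_svm":
            out["weights"] = self.model.coef_.ravel().tolist()
            out["intercept"] = float(self.model.intercept_[0])
            cal = self.calibration
        else:
            out["projection"] = self.model.projection.tolist()
            out["eigenvalues"] = self.model.eigenvalues.tolist()
            cal = self.model.calibration
        out["calibration"] = {
            "coef": cal.coef_.ravel().tolist(),
            "intercept": float(cal.intercept_[0]),
        }
        return out


def fit_linear_svm(
    data: LabeledProfileMatrix,
    C: float = 1.0,
    calibration_scores: np.ndarray | None = None,
    calibration_labels: np.ndarray | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Class-weight-balanced soft-margin linear SVM with Platt calibration."""
    X, y = data.X, data.y
    if len(np.unique(y)) < 2:
        raise ValueError("fit_linear_svm requires both classes present")
    # primal solve (compounds outnumber genes on profile matrices); tol 1e-3
    # leaves decision values within ~1e-3 relative of a tightly converged fit
    svc = LinearSVC(C=C, class_weight="balanced", random_state=seed,
                    max_iter=20_000, dual=False, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional liblinear ConvergenceWarning on tiny folds
        svc.fit(X, y)
    if calibration_scores is not None:
        cal = _fit_platt(calibration_scores, calibration_labels)
    else:
        cal = _fit_platt(svc.decision_function(X), y)
    return TrainedClassifier(
        kind="linear_svm", model=svc, calibration=cal,
        hyperparameters={"C": C}, n_features=X.shape[1],
    )


def wrap_mmc(model: MMCModel, n_features: int) -> TrainedClassifier:
    return TrainedClassifier(
        kind="mmc", model=model, calibration=model.calibration,
        hyperparameters={"k": model.k}, n_features=n_features,
    )


class _LinearDecision:
    """Minimal linear decision function reloaded from the JSON container."""

    def __init__(self, weights: np.ndarray, intercept: float):
        self.coef_ = np.atleast_2d(np.asarray(weights, float))
        self.intercept_ = np.array([float(intercept)])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.coef_.ravel() + self.intercept_[0]


def _logistic_from_json(d: dict) -> LogisticRegression:
    lr = LogisticRegression()
    lr.coef_ = np.atleast_2d(np.asarray(d["coef"], float))
    lr.intercept_ = np.array([float(d["intercept"])])
    lr.classes_ = np.array([0, 1])
    return lr


def classifier_from_json(d: dict) -> TrainedClassifier:
    """Rebuild a trained classifier from :meth:`TrainedClassifier.to_json`."""
    cal = _logistic_from_json(d["calibration"])
    if d["kind"] == "linear_svm":
        model = _LinearDecision(d["weights"], d["intercept"])
        return TrainedClassifier(
            kind="linear_svm", model=model, calibration=cal,
            hyperparameters=d["hyperparameters"], n_features=d["n_features"],
        )
    projection = np.asarray(d["projection"], float)
    mmc = MMCModel(
        projection=projection,
        eigenvalues=np.asarray(d["eigenvalues"], float),
        k=projection.shape[1],
        class_means={},
        calibration=cal,
    )
    return TrainedClassifier(
        kind="mmc", model=mmc, calibration=cal,
        hyperparameters=d["hyperparameters"], n_features=d["n_features"],
    )


def f_score(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Positive-class F1 plus per-class accuracy (recall of each class).

    With no positive truths and no positive predictions F1 is defined as 0
    with a warning, so degenerate folds stay comparable.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    if tp + fp + fn == 0:
        warnings.warn("no positive truths or predictions; F1 defined as 0", stacklevel=2)
        f1 = 0.0
    else:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    acc_pos = tp / (tp + fn) if tp + fn else float("nan")
    acc_neg = tn / (tn + fp) if tn + fp else float("nan")
    return {"f1": f1, "accuracy_positive": acc_pos, "accuracy_negative": acc_neg}


def gene_importance(
    model_predictions: np.ndarray, X: LabeledProfileMatrix | np.ndarray
) -> np.ndarray:
    """Pearson correlation of each gene's profile level with the prediction
    outcomes; zero-variance genes score 0 by convention."""
    if isinstance(X, LabeledProfileMatrix):
        X = X.X
    X = np.asarray(X, float)
    p = np.asarray(model_predictions, float)
    if X.shape[0] != p.shape[0]:
        raise ValueError("predictions must align with rows of X")
    if X.shape[0] < 3:
        raise ValueError("gene importance requires >= 3 compounds")
    Xc = X - X.mean(axis=0)
    pc = p - p.mean()
    x_sd = np.sqrt((Xc ** 2).sum(axis=0))
    p_sd = np.sqrt((pc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc.T @ pc) / (x_sd * p_sd)
    corr[~np.isfinite(corr)] = 0.0
    # exact-range check: a constant column is zero-variance even when its
    # centred values carry float residue
    corr[np.ptp(X, axis=0) == 0] = 0.0
    return corr


def importance_table(importance: np.ndarray, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Sortable importance table (gene_id, mean_importance, rank)."""
    df = pd.DataFrame({"gene_id": list(gene_ids), "mean_importance": importance})
    df = df.sort_values(["mean_importance", "gene_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def export_rnk(importance: np.ndarray, gene_ids: Sequence[str], path: str | Path) -> None:
    """Write a ranked gene list (.rnk: gene <tab> score, descending) for
    external preranked gene-set enrichment tools."""
    df = importance_table(importance, gene_ids)
    df[["gene_id", "mean_importance"]].to_csv(path, sep="\t", header=False, index=False)
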