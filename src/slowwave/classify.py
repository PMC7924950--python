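"""Linear-SVM circuit classification and boundary analysis.

Cells (one mean feature vector each) are classified with a soft-margin
linear support vector machine on standardized features.  Feature
relevance is ranked by recursive feature elimination (RFE); accuracy is
estimated with stratified k-fold cross-validation or leave-one-animal-
out validation, always fitting the standardizer on training cells only.

Because an SVM can only assign one of its training categories, a third
group of cells is analyzed geometrically instead: all cells are
projected onto the hypervector orthogonal to the separating hyperplane
and the projected distributions are compared (rank-sum), which shows
where the new group lies along the classification axis rather than
forcing a binary label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .stats import rank_sum

__all__ = [
    "LinearClassifier",
    "RfeResult",
    "ProjectionResult",
    "fit_linear_svm",
    "cross_validate",
    "rfe_rank",
    "leave_one_animal_out",
    "project_to_hypervector",
    "compare_projection_distributions",
    "label_pathway_from_light_response",
]

log = logging.getLogger(__name__)


@dataclass
class LinearClassifier:
    """Standardizer + linear-SVM hyperplane.

    ``weights`` and ``intercept`` live in standardized feature space;
    ``classes`` maps the sign of the decision function to labels
    (negative -> classes[0], positive -> classes[1]).
    """

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    intercept: float
    classes: list

    def decision_function(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        Z = (X - self.mean) / self.scale
        return Z @ self.weights + self.intercept

    def predict(self, features) -> np.ndarray:
        d = self.decision_function(features)
        return np.where(d > 0, self.classes[1], self.classes[0])

    def to_json(self, path: str | Path) -> None:
        payload = {"feature_names": self.feature_names,
                   "mean": self.mean.tolist(), "scale": self.scale.tolist(),
                   "weights": self.weights.tolist(), "intercept": self.intercept,
                   "classes": [str(c) for c in self.classes]}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearClassifier":
        d = json.loads(Path(path).read_text())
        return cls(d["feature_names"], np.asarray(d["mean"]), np.asarray(d["scale"]),
                   np.asarray(d["weights"]), float(d["intercept"]), d["classes"])


@dataclass
class RfeResult:
    """RFE feature ranking with the cross-validated accuracy curve."""

    ranking: list[str]                 # most to least relevant
    accuracy_curve: np.ndarray         # mean CV accuracy vs retained count (1..p)
    accuracy_sd: np.ndarray


@dataclass
class ProjectionResult:
    """Scalar projections of cells along the classification hypervector."""

    projections: np.ndarray
    labels: np.ndarray
    group_summaries: pd.DataFrame = field(default=None)


def _as_matrix(features, names: list[str] | None = None) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        if names is not None:
            missing = [n for n in names if n not in features.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            return features[names].to_numpy(dtype=float)
        return features.to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if names is not None and X.shape[1] != len(names):
        raise ValueError("feature count does not match the model's feature names")
    return X


def _feature_names(features) -> list[str]:
    if isinstance(features, pd.DataFrame):
        return list(features.columns)
    return [f"x{i}" for i in range(np.asarray(features).shape[1])]


def fit_linear_svm(features, labels, c_param: float = 1.0) -> LinearClassifier:
    """Fit a soft-margin linear SVM on standardized features.

    Standardization statistics come from the supplied (training) cells
    only; the returned weights live in standardized space.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 cells per class")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale == 0):
        scale = np.where(scale == 0, 1.0, scale)
        log.warning("constant feature(s): left unscaled")
    Z = (X - mean) / scale
    yy = np.where(y == classes[1], 1, -1)
    svc = SVC(kernel="linear", C=c_param)
    svc.fit(Z, yy)
    return LinearClassifier(_feature_names(features), mean, scale,
                            svc.coef_.ravel().copy(), float(svc.intercept_[0]),
                            classes)


def cross_validate(features, labels, k: int = 10, repeats: int = 1,
                   seed: int | None = None, c_param: float = 1.0
                   ) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold cross-validated accuracy.

    The standardizer and SVM are fit on training folds only.  Returns
    (mean, SD, per-fold accuracies) over all folds and repeats.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class size {counts.min()}")
    names = _feature_names(features)
    accs = []
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for train, test in skf.split(X, y):
            model = fit_linear_svm(pd.DataFrame(X[train], columns=names), y[train],
                                   c_param)
            pred = model.predict(pd.DataFrame(X[test], columns=names))
            accs.append(float(np.mean(pred == y[test])))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std()), accs


def rfe_rank(features, labels, k: int = 10, seed: int | None = None,
             c_param: float = 1.0, compute_curve: bool = True) -> RfeResult:
    """Recursive feature elimination with a linear SVM.

    At each step the feature with the smallest absolute standardized
    weight is removed (ties broken toward the lower feature index).
    The accuracy curve re-fits and cross-validates on the top-m feature
    subsets of the final ranking for every m.
    """
    X = _as_matrix(features)
    names = _feature_names(features)
    y = np.asarray(labels)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        model = fit_linear_svm(pd.DataFrame(X[:, remaining],
                                            columns=[names[i] for i in remaining]), y,
                               c_param)
        w = np.abs(model.weights)
        drop_local = int(np.lexsort((np.arange(w.size), w))[0])
        eliminated.append(remaining.pop(drop_local))
    eliminated.append(remaining[0])
    ranking_idx = eliminated[::-1]          # last survivor = most relevant
    ranking = [names[i] for i in ranking_idx]

    p = X.shape[1]
    curve = np.full(p, np.nan)
    curve_sd = np.full(p, np.nan)
    if compute_curve:
        for m in range(1, p + 1):
            cols = ranking_idx[:m]
            mu, sd, _ = cross_validate(pd.DataFrame(X[:, cols],
                                                    columns=[names[i] for i in cols]),
                                       y, k=k, seed=seed, c_param=c_param)
            curve[m - 1] = mu
            curve_sd[m - 1] = sd
    return RfeResult(ranking, curve, curve_sd)


def leave_one_animal_out(features, labels, animal_ids, c_param: float = 1.0
                         ) -> tuple[pd.DataFrame, float, list]:
    """One-animal-out validation.

    For each animal, all its cells are held out; the standardizer and
    SVM are fit on the remaining animals' cells and the held-out cells
    are then predicted.  Folds whose training set collapses to a single
    class are flagged and skipped.  Returns (per-cell predictions,
    overall accuracy over predicted cells, flagged animals).
    """
    X = _as_matrix(features)
    names = _feature_names(features)
    y = np.asarray(labels)
    animals = np.asarray(animal_ids)
    if pd.unique(animals).size < 2:
        raise ValueError("need at least 2 animals")
    rows = []
    flagged = []
    for animal in pd.unique(animals):
        hold = animals == animal
        y_train = y[~hold]
        if pd.unique(y_train).size < 2:
            log.warning("animal %s holds all cells of one class; fold flagged", animal)
            flagged.append(animal)
            continue
        model = fit_linear_svm(pd.DataFrame(X[~hold], columns=names), y_train, c_param)
        pred = model.predict(pd.DataFrame(X[hold], columns=names))
        for i, p_lab in zip(np.where(hold)[0], pred):
            rows.append({"index": int(i), "animal_id": animal,
                         "true": y[i], "predicted": p_lab})
    table = pd.DataFrame(rows)
    acc = float(np.mean(table["true"] == table["predicted"])) if len(table) else float("nan")
    return table, acc, flagged


def project_to_hypervector(model: LinearClassifier, features,
                           labels=None) -> ProjectionResult:
    """Project cells onto the unit normal of the separating hyperplane.

    The projection of a cell is its signed distance to the boundary in
    standardized feature space: z . w/|w| + b/|w|.  The sign of the
    projection therefore reproduces the model's predicted label for
    every cell.
    """
    X = _as_matrix(features, model.feature_names)
    Z = (X - model.mean) / model.scale
    norm = np.linalg.norm(model.weights)
    if norm == 0:
        raise ValueError("degenerate model: zero weight vector")
    proj = Z @ (model.weights / norm) + model.intercept / norm
    labels = np.asarray(labels) if labels is not None else np.full(proj.size, "", dtype=object)
    summaries = None
    if labels is not None and labels.size:
        df = pd.DataFrame({"projection": proj, "group": labels})
        summaries = df.groupby("group")["projection"].agg(["count", "mean", "std", "median"])
    return ProjectionResult(proj, labels, summaries)


def compare_projection_distributions(proj_a, proj_b) -> float:
    """Two-sided rank-sum p-value between two projection distributions."""
    a = np.asarray(proj_a, dtype=float)
    b = np.asarray(proj_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both projections must be non-empty")
    if a.size < 3 or b.size < 3:
        log.warning("fewer than 3 cells on one side: rank-sum p is coarse")
    return rank_sum(a, b).p_value


def label_pathway_from_light_response(trials: np.ndarray, rate_hz: float,
                                      pulse_onset_s: float,
                                      threshold_mv: float = 4.0,
                                      latency_window_s: tuple[float, float] = (0.0008, 0.005),
                                      baseline_s: float = 0.01) -> str:
    """Classify a cell as indirect or putative direct from light pulses.

    Channelrhodopsin-tagged (indirect-pathway) cells respond to the
    light pulse with a fast step-like depolarization; a cell is labeled
    ``indirect`` when the median across pulses of the depolarization
    inside the latency window reaches ``threshold_mv`` over the
    pre-pulse baseline, otherwise ``putative_direct``.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    i_on = int(round(pulse_onset_s * rate_hz))
    i_b0 = max(i_on - int(round(baseline_s * rate_hz)), 0)
    j0 = i_on + int(round(latency_window_s[0] * rate_hz))
    j1 = i_on + max(int(round(latency_window_s[1] * rate_hz)), j0 + 1)
    base = trials[:, i_b0:i_on].mean(axis=1)
    depol = trials[:, j0:j1].max(axis=1) - base
    return "indirect" if float(np.median(depol)) >= threshold_mv else "putative_direct"
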