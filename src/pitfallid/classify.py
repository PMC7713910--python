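"""The five classifier families, grid tuning, and probability matrices.

Five algorithm families are compared on the standardized 68-feature vectors:
k-nearest neighbors (k tuned over 1..25), linear discriminant analysis,
Gaussian naive Bayes, random forests (mtry — features per split — tuned over
1..10, 500 trees), and a single-hidden-layer neural network (hidden units
tuned over 1..25).  Gridded algorithms select the value maximizing top-1
accuracy, either by 5-fold cross-validation inside the training set
(default) or on a supplied evaluation set ("paper-fidelity" mode, which
reproduces protocols that tuned on the test split and is flagged as leakage
in the model metadata).

Estimators follow the scikit-learn contract (``fit`` / ``predict`` /
``predict_proba``, fitted attributes with trailing underscores) and compose
with sklearn tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

ALGORITHMS = ("KNN", "LDA", "NB", "RF", "ANN", "baseline")

DEFAULT_GRIDS: dict[str, tuple[int, ...]] = {
    "KNN": tuple(range(1, 26)),
    "RF": tuple(range(1, 11)),
    "ANN": tuple(range(1, 26)),
}

_GRID_RANGES = {"KNN": (1, 25), "RF": (1, 10), "ANN": (1, 25)}


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus its tuning grid and mode."""

    algorithm: str
    grid: tuple[int, ...] | None = None
    tuning_mode: str = "inner-cv"  # "inner-cv" | "paper-fidelity"
    seed: int = 0
    rf_trees: int = 500
    ann_max_iter: int = 10000
    ann_retries: int = 3

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ClassifyError(f"unknown algorithm {self.algorithm!r}")
        if self.tuning_mode not in ("inner-cv", "paper-fidelity"):
            raise ClassifyError(f"unknown tuning mode {self.tuning_mode!r}")
        grid = self.grid
        if grid is None and self.algorithm in DEFAULT_GRIDS:
            grid = DEFAULT_GRIDS[self.algorithm]
            object.__setattr__(self, "grid", grid)
        if grid is not None:
            lo, hi = _GRID_RANGES.get(self.algorithm, (1, 10**9))
            if not grid or any(
                (not float(g).is_integer()) or g < lo or g > hi for g in grid
            ):
                raise ClassifyError(
                    f"{self.algorithm} grid values must be integers in [{lo}, {hi}]"
                )


@dataclass
class PredictionMatrix:
    """Specimens x classes probability matrix with a deterministic ranking.

    Ties in probability are broken by descending training-class frequency,
    then lexicographic class name, so top-k sets are reproducible.
    """

    proba: np.ndarray
    classes: np.ndarray
    class_frequency: dict[str, int]

    def __post_init__(self) -> None:
        self.proba = np.asarray(self.proba, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.proba.ndim != 2 or self.proba.shape[1] != len(self.classes):
            raise ClassifyError("probability matrix shape mismatch")
        if (self.proba < -1e-9).any() or (self.proba > 1 + 1e-9).any():
            raise ClassifyError("probabilities outside [0, 1]")
        sums = self.proba.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ClassifyError("probability rows must sum to 1")

    def ranking(self) -> np.ndarray:
        """Class indices sorted per row: probability desc, frequency desc, name asc."""
        freq = np.array([self.class_frequency.get(c, 0) for c in self.classes])
        name_rank = np.argsort(np.argsort(self.classes.astype(str)))
        # lexsort: last key is primary
        out = np.empty(self.proba.shape, dtype=int)
        for i, row in enumerate(self.proba):
            out[i] = np.lexsort((name_rank, -freq, -row))
        return out

    def top_labels(self, k: int = 1) -> np.ndarray:
        idx = self.ranking()[:, :k]
        return self.classes[idx]

    def restrict(self, allowed: set[str]) -> "PredictionMatrix":
        """Drop classes outside ``allowed``, renormalizing each row.

        Rows whose allowed probability mass is zero fall back to the
        training-frequency distribution over the allowed classes, which
        reproduces "rank by training frequency" deterministically.
        """
        keep = np.array([c in allowed for c in self.classes])
        if not keep.any():
            raise ClassifyError("no model class inside the allowed set")
        sub = self.proba[:, keep]
        classes = self.classes[keep]
        freq = np.array(
            [self.class_frequency.get(c, 0) for c in classes], dtype=float
        )
        freq = freq + 1e-12
        sums = sub.sum(axis=1, keepdims=True)
        dead = sums[:, 0] <= 0
        sub = np.where(dead[:, None], freq / freq.sum(), sub / np.maximum(sums, 1e-300))
        sub = sub / sub.sum(axis=1, keepdims=True)
        return PredictionMatrix(sub, classes, self.class_frequency)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proba, columns=self.classes.astype(str))


def _base_estimator(algorithm: str, param: int | None, spec: ModelSpec):
    if algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=int(param), metric="euclidean")
    if algorithm == "LDA":
        return LinearDiscriminantAnalysis()
    if algorithm == "NB":
        return GaussianNB()
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=spec.rf_trees,
            max_features=int(param),
            random_state=spec.seed,
            n_jobs=1,
        )
    if algorithm == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=(int(param),),
            activation="logistic",
            solver="lbfgs",
            max_iter=spec.ann_max_iter,
            tol=1e-5,
            random_state=spec.seed,
        )
    raise ClassifyError(f"no estimator for {algorithm!r}")


def _fit_one(algorithm: str, param: int | None, spec: ModelSpec, X, y):
    """Fit a single grid point, with the LDA/ANN fallback rules."""
    if algorithm == "LDA":
        est = _base_estimator(algorithm, param, spec)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            est.fit(X, y)
        if any("collinear" in str(w.message).lower() for w in caught):
            warnings.warn(
                "singular within-class covariance; refitting LDA with "
                "ridge shrinkage",
                stacklevel=2,
            )
            est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            est.fit(X, y)
        return est
    if algorithm == "ANN":
        # stopping rule: loss change < tol or the epoch cap, whichever first;
        # hitting the cap is a stop, not a failure.  Genuine optimizer
        # failures (non-finite loss, internal errors) get seeded restarts.
        last_err = None
        for attempt in range(spec.ann_retries):
            est = MLPClassifier(
                hidden_layer_sizes=(int(param),),
                activation="logistic",
                solver="lbfgs",
                max_iter=spec.ann_max_iter,
                tol=1e-5,
                random_state=spec.seed + 1000 * attempt,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est.fit(X, y)
            except (ValueError, FloatingPointError) as err:  # pragma: no cover
                last_err = str(err)
                continue
            if np.isfinite(est.loss_):
                return est
            last_err = f"non-finite loss {est.loss_!r}"
        raise ClassifyError(
            f"ANN failed to converge after {spec.ann_retries} seeded restarts: "
            f"{last_err}"
        )
    est = _base_estimator(algorithm, param, spec)
    est.fit(X, y)
    return est


class TunedTaxonClassifier(ClassifierMixin, BaseEstimator):
    """Grid-tuned wrapper around one of the five algorithm families.

    Parameters mirror :class:`ModelSpec`.  ``fit(X, y)`` tunes by inner
    cross-validation; ``fit(X, y, eval_X=..., eval_y=...)`` under
    ``tuning_mode="paper-fidelity"`` selects the grid value on the supplied
    evaluation set instead (recorded in ``metadata_["leakage"]``).
    """

    def __init__(
        self,
        algorithm: str = "LDA",
        grid: tuple[int, ...] | None = None,
        tuning_mode: str = "inner-cv",
        seed: int = 0,
        cv_folds: int = 5,
        rf_trees: int = 500,
        ann_max_iter: int = 10000,
    ):
        self.algorithm = algorithm
        self.grid = grid
        self.tuning_mode = tuning_mode
        self.seed = seed
        self.cv_folds = cv_folds
        self.rf_trees = rf_trees
        self.ann_max_iter = ann_max_iter

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            algorithm=self.algorithm,
            grid=self.grid,
            tuning_mode=self.tuning_mode,
            seed=self.seed,
            rf_trees=self.rf_trees,
            ann_max_iter=self.ann_max_iter,
        )

    def fit(self, X, y, eval_X=None, eval_y=None):
        spec = self._spec()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ClassifyError("need at least 2 classes to train")
        self.classes_ = classes
        self.class_frequency_ = dict(zip(classes.astype(str), counts.astype(int)))
        self.feature_count_ = X.shape[1]
        grid = spec.grid
        if grid is None:
            self.best_param_ = None
            self.estimator_ = _fit_one(spec.algorithm, None, spec, X, y)
            self.metadata_ = {"leakage": False, "tuning": "none"}
            return self
        if spec.tuning_mode == "paper-fidelity":
            if eval_X is None or eval_y is None:
                raise ClassifyError(
                    "paper-fidelity tuning needs eval_X/eval_y (it selects the "
                    "grid value on that set)"
                )
            eval_X = np.asarray(eval_X, dtype=float)
            eval_y = np.asarray(eval_y, dtype=object)
            best, best_acc, best_est = None, -1.0, None
            for g in grid:
                est = _fit_one(spec.algorithm, g, spec, X, y)
                acc = float(np.mean(est.predict(eval_X) == eval_y))
                if acc > best_acc:
                    best, best_acc, best_est = g, acc, est
            self.best_param_, self.estimator_ = best, best_est
            self.metadata_ = {
                "leakage": True,
                "tuning": "paper-fidelity",
                "selection_accuracy": best_acc,
            }
            return self
        # inner 5-fold CV on the training set
        min_class = int(counts.min())
        n_splits = max(2, min(self.cv_folds, min_class))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
        best, best_acc = None, -1.0
        for g in grid:
            accs = []
            for tr, va in cv.split(X, y):
                est = _fit_one(spec.algorithm, g, spec, X[tr], y[tr])
                accs.append(float(np.mean(est.predict(X[va]) == y[va])))
            acc = float(np.mean(accs))
            if acc > best_acc:
                best, best_acc = g, acc
        self.best_param_ = best
        self.estimator_ = _fit_one(spec.algorithm, best, spec, X, y)
        self.metadata_ = {
            "leakage": False,
            "tuning": f"inner-cv({n_splits})",
            "selection_accuracy": best_acc,
        }
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.feature_count_:
            raise ClassifyError(
                f"feature count mismatch: model expects {self.feature_count_}, "
                f"got {X.shape[1]}"
            )
        proba = self.estimator_.predict_proba(X)
        # guard against tiny numerical drift off the simplex
        proba = np.clip(proba, 0.0, None)
        return proba / proba.sum(axis=1, keepdims=True)

    def prediction_matrix(self, X) -> PredictionMatrix:
        return PredictionMatrix(
            self.predict_proba(X), self.classes_, self.class_frequency_
        )

    def predict(self, X) -> np.ndarray:
        return self.prediction_matrix(X).top_labels(1)[:, 0]


class MostCommonBaseline(ClassifierMixin, BaseEstimator):
    """Chance-level reference: always predicts the most frequent training
    species (lexicographically first on ties) with probability 1."""

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        classes, counts = np.unique(y, return_counts=True)
        self.classes_ = classes
        self.class_frequency_ = dict(zip(classes.astype(str), counts.astype(int)))
        # np.unique sorts lexicographically, so argmax takes the first on ties
        self.most_common_ = classes[int(np.argmax(counts))]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "most_common_")
        n = len(np.asarray(X))
        proba = np.zeros((n, len(self.classes_)))
        proba[:, int(np.where(self.classes_ == self.most_common_)[0][0])] = 1.0
        return proba

    def prediction_matrix(self, X) -> PredictionMatrix:
        return PredictionMatrix(
            self.predict_proba(X), self.classes_, self.class_frequency_
        )

    def predict(self, X) -> np.ndarray:
        n = len(np.asarray(X))
        return np.full(n, self.most_common_, dtype=object)


# ---------------------------------------------------------------------------
# thin functional surface


def train(
    spec: ModelSpec,
    X,
    y,
    eval_X=None,
    eval_y=None,
):
    """Fit one model per ``spec`` on standardized training rows."""
    if spec.algorithm == "baseline":
        return MostCommonBaseline().fit(X, y)
    model = TunedTaxonClassifier(
        algorithm=spec.algorithm,
        grid=spec.grid,
        tuning_mode=spec.tuning_mode,
        seed=spec.seed,
        rf_trees=spec.rf_trees,
        ann_max_iter=spec.ann_max_iter,
    )
    return model.fit(X, y, eval_X=eval_X, eval_y=eval_y)


def predict_proba(model, X) -> PredictionMatrix:
    """A validated :class:`PredictionMatrix` for ``X``."""
    return model.prediction_matrix(X)


def baseline_most_common(X, y) -> MostCommonBaseline:
    return MostCommonBaseline().fit(X, y)


def save_model(model, path) -> None:
    """Serialize a fitted model bundle (joblib blob + JSON metadata sidecar)."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "format": "pitfallid-model/1",
        "algorithm": getattr(model, "algorithm", type(model).__name__),
        "best_param": getattr(model, "best_param_", None),
        "classes": [str(c) for c in model.classes_],
        "metadata": getattr(model, "metadata_", {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path):
    import joblib

    return joblib.load(path)
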