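"""Two-stage prediction: HD/control classification, then subscore regression.

The modelling surface is scikit-learn shaped:

* :class:`LassoSelector` — an L1-path feature-selection transformer that
  keeps at most ``cap`` (default 19, i.e. "fewer than 20") of the 312
  features, with the penalty chosen by inner 5-fold cross-validation over a
  100-point log-spaced path and then tightened along the path until the cap
  holds;
* :class:`Stage1Classifier` — standardize -> LASSO-select -> {LDA, linear
  SVM, KNN};
* :class:`Stage2Regressor` — standardize -> LASSO-select -> {linear SVR,
  pruned decision tree, exponential-kernel Gaussian process}, trained on
  symptomatic subjects only, predictions clipped to the subscore range;
* :class:`TwoStageScorer` — the combined predictor: subjects classified as
  controls receive a score of zero, subjects classified as HD (including
  misclassified controls) receive the stage-2 regression prediction.

``loo_stage1`` / ``loo_stage2`` / ``two_stage_predict`` run these estimators
under leave-one-out cross-validation with feature selection and
standardization refit inside every round, so the held-out subject never
touches the trained model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import SelectorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "SubscoreSpec",
    "SUBSCORE_SPECS",
    "CVRoundResult",
    "ModelingError",
    "LassoSelector",
    "Stage1Classifier",
    "Stage2Regressor",
    "TwoStageScorer",
    "loo_stage1",
    "loo_stage2",
    "two_stage_predict",
    "composite_strategies",
]

logger = logging.getLogger(__name__)

STAGE1_FAMILIES = ("lda", "svm", "knn")
STAGE2_FAMILIES = ("svm", "tree", "gp")
DEFAULT_CAP = 19  # "fewer than 20 features"


class ModelingError(ValueError):
    pass


@dataclass(frozen=True)
class SubscoreSpec:
    """A UHDRS-TMS subscore and its achievable range (minimum is 0)."""

    name: str
    range: int


#: The seven motor subscores plus their composite sum.  Single items are
#: rated 0-4; total chorea and total dystonia aggregate five body sites
#: (each arm, each leg, trunk) at 4 points each, hence a range of 20.
SUBSCORE_SPECS: dict[str, SubscoreSpec] = {
    "arm_rigidity_left": SubscoreSpec("arm_rigidity_left", 4),
    "arm_rigidity_right": SubscoreSpec("arm_rigidity_right", 4),
    "total_chorea": SubscoreSpec("total_chorea", 20),
    "total_dystonia": SubscoreSpec("total_dystonia", 20),
    "bradykinesia": SubscoreSpec("bradykinesia", 4),
    "gait": SubscoreSpec("gait", 4),
    "tandem_gait": SubscoreSpec("tandem_gait", 4),
    "composite": SubscoreSpec("composite", 60),
}


@dataclass(frozen=True)
class CVRoundResult:
    """One leave-one-out round: who was held out, what was selected, the call."""

    held_out_id: str
    selected_features: tuple[str, ...]
    prediction: float | str


# ---------------------------------------------------------------------------
# feature selection


class LassoSelector(SelectorMixin, BaseEstimator):
    """L1-path feature selection capped at ``cap`` features.

    Parameters
    ----------
    task : {"regress", "classify"}
        Target kind.  Class labels are selected with a plain LASSO on the
        0/1 class indicator by default (``classify_loss="linear"``, the
        classical screening approach); ``classify_loss="logistic"`` uses an
        L1-penalised logistic path instead.
    cap : int
        Maximum number of selected features (at least one is always kept).
    n_alphas : int
        Points on the log-spaced penalty path.
    cv : int
        Inner folds used to pick the penalty.
    standardize : bool
        Z-score columns with the training statistics before fitting.  Turn
        off when a scaler already precedes the selector in a pipeline.
    """

    def __init__(
        self,
        task: str = "regress",
        cap: int = DEFAULT_CAP,
        n_alphas: int = 100,
        cv: int = 5,
        cv_repeats: int = 5,
        classify_loss: str = "linear",
        standardize: bool = True,
        random_state: int | None = None,
    ):
        self.task = task
        self.cap = cap
        self.n_alphas = n_alphas
        self.cv = cv
        self.cv_repeats = cv_repeats
        self.classify_loss = classify_loss
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if n < 3:
            raise ModelingError("need at least 3 samples for penalty selection")
        if self.task not in ("regress", "classify"):
            raise ModelingError(f"unknown selection task {self.task!r}")

        variable = X.std(axis=0) > 0
        if not variable.all():
            logger.debug(
                "excluding %d all-constant columns before LASSO", (~variable).sum()
            )
        Xv = X[:, variable]
        if self.standardize:
            Xv = StandardScaler().fit_transform(Xv)

        if self.task == "regress":
            nnz_path = self._regression_path(Xv, y.astype(float))
        else:
            classes = np.unique(y)
            if classes.size != 2:
                raise ModelingError(
                    f"stage-1 selection needs exactly 2 classes, got {classes.tolist()}"
                )
            if self.classify_loss == "linear":
                indicator = (y == classes[1]).astype(float)
                nnz_path = self._regression_path(Xv, indicator)
            elif self.classify_loss == "logistic":
                nnz_path = self._classification_path(Xv, y)
            else:
                raise ModelingError(f"unknown classify_loss {self.classify_loss!r}")

        mask = np.zeros(p, dtype=bool)
        mask[np.flatnonzero(variable)[nnz_path]] = True
        self.support_mask_ = mask
        self.n_selected_ = int(mask.sum())
        return self

    # -- penalty paths ------------------------------------------------------

    def _regression_path(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        y = y.astype(float)
        yc = y - y.mean()
        if np.allclose(yc, 0):
            logger.debug("constant regression target; keeping the single best column")
            corr = np.abs(X.T @ (y - y.mean() + 1e-12))
            return np.array([int(np.argmax(corr))])
        n = X.shape[0]
        alpha_max = np.max(np.abs(X.T @ yc)) / n
        alphas = np.logspace(
            np.log10(alpha_max), np.log10(alpha_max * 1e-3), self.n_alphas
        )
        # repeated inner K-fold CV over the shared path (averaging over
        # repetitions stabilises the penalty choice at these sample sizes)
        mse = np.zeros(self.n_alphas)
        base = 0 if self.random_state is None else int(self.random_state)
        with warnings.catch_warnings():
            # the small-alpha end of the path legitimately stops early; the
            # selected penalty never sits there
            warnings.simplefilter("ignore", ConvergenceWarning)
            for rep in range(self.cv_repeats):
                cv = KFold(
                    n_splits=min(self.cv, n), shuffle=True, random_state=base + rep
                )
                for tr, te in cv.split(X):
                    mu = y[tr].mean()
                    _, coefs, _ = lasso_path(X[tr], y[tr] - mu, alphas=alphas)
                    pred = X[te] @ coefs + mu  # path fitted on centered y
                    resid = pred - y[te][:, None]
                    mse += np.mean(resid**2, axis=0)
            best = int(np.argmin(mse))
            _, coefs, _ = lasso_path(X, yc, alphas=alphas)
        nnz = (np.abs(coefs) > 1e-12).sum(axis=0)
        # tighten the penalty (walk toward alpha_max) until the cap holds
        idx = best
        while idx > 0 and nnz[idx] > self.cap:
            idx -= 1
        # guarantee at least one feature
        while idx < self.n_alphas - 1 and nnz[idx] < 1:
            idx += 1
        if nnz[idx] < 1 or nnz[idx] > self.cap:
            logger.debug("cap-constrained path degenerate; using strongest column")
            corr = np.abs(X.T @ (y - y.mean()))
            return np.array([int(np.argmax(corr))])
        return np.flatnonzero(np.abs(coefs[:, idx]) > 1e-12)

    def _classification_path(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        classes = np.unique(y)
        n = X.shape[0]
        Cs = np.logspace(-3, 2, self.n_alphas)
        n_splits = min(self.cv, int(np.min(np.bincount(pd.factorize(y)[0]))))
        n_splits = max(n_splits, 2)
        acc = np.zeros(self.n_alphas)
        base = 0 if self.random_state is None else int(self.random_state)
        for rep in range(self.cv_repeats):
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=base + rep)
            for tr, te in cv.split(X, y):
                for j, C in enumerate(Cs):
                    clf = LogisticRegression(
                        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000,
                        random_state=self.random_state,
                    )
                    clf.fit(X[tr], y[tr])
                    acc[j] += np.mean(clf.predict(X[te]) == y[te])
        best = int(np.argmax(acc))
        # refit the whole path on the full training fold, record sparsity
        support_by_j: list[np.ndarray] = []
        for C in Cs:
            clf = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000,
                random_state=self.random_state,
            )
            clf.fit(X, y)
            support_by_j.append(np.flatnonzero(np.abs(clf.coef_[0]) > 1e-12))
        idx = best
        while idx > 0 and support_by_j[idx].size > self.cap:
            idx -= 1
        while idx < self.n_alphas - 1 and support_by_j[idx].size < 1:
            idx += 1
        sel = support_by_j[idx]
        if sel.size < 1 or sel.size > self.cap:
            logger.debug("cap-constrained logistic path degenerate; strongest column")
            y01 = (y == classes[1]).astype(float)
            corr = np.abs(X.T @ (y01 - y01.mean()))
            return np.array([int(np.argmax(corr))])
        return sel

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


# ---------------------------------------------------------------------------
# stage estimators


def _stage1_model(family: str, random_state: int | None):
    if family == "lda":
        # Ledoit-Wolf shrinkage: the selected-feature count approaches the
        # training-fold size, where the sample covariance is ill-conditioned
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if family == "svm":
        return SVC(kernel="linear", C=1.0, random_state=random_state)
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ModelingError(
        f"unknown stage-1 family {family!r}; expected one of {STAGE1_FAMILIES}"
    )


class Stage1Classifier(ClassifierMixin, BaseEstimator):
    """Binary HD/control classifier: scale -> LASSO-select -> family model."""

    def __init__(
        self,
        family: str = "lda",
        cap: int = DEFAULT_CAP,
        random_state: int | None = None,
    ):
        self.family = family
        self.cap = cap
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ModelingError(
                f"training fold must contain both classes, got {classes.tolist()}"
            )
        if counts.min() < 2:
            raise ModelingError("need at least 2 subjects per class")
        self.pipeline_ = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "select",
                    LassoSelector(
                        task="classify",
                        cap=self.cap,
                        standardize=False,
                        random_state=self.random_state,
                    ),
                ),
                ("clf", _stage1_model(self.family, self.random_state)),
            ]
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["clf"].classes_
        self.selected_indices_ = np.flatnonzero(
            self.pipeline_.named_steps["select"].support_mask_
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = validate_data(self, X, dtype=float, reset=False)
        return self.pipeline_.predict(X)


def _exponential_gp(random_state: int | None) -> GaussianProcessRegressor:
    # exponential (Ornstein-Uhlenbeck) covariance = Matern with nu = 1/2
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=1.0, length_scale_bounds=(1e-2, 1e3), nu=0.5
    ) + WhiteKernel(1e-2, (1e-8, 1e1))
    return GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=5,
        random_state=random_state,
    )


class Stage2Regressor(RegressorMixin, BaseEstimator):
    """Subscore regressor trained on symptomatic subjects only.

    Predictions are continuous, clipped to ``[0, subscore_range]``;
    ``round_to_int=True`` additionally rounds to the integer scale.
    """

    def __init__(
        self,
        family: str = "gp",
        subscore_range: int = 4,
        cap: int = DEFAULT_CAP,
        round_to_int: bool = False,
        random_state: int | None = None,
    ):
        self.family = family
        self.subscore_range = subscore_range
        self.cap = cap
        self.round_to_int = round_to_int
        self.random_state = random_state

    def _make_model(self, y: np.ndarray):
        if self.family == "svm":
            eps = 0.1 * float(np.std(y))
            return SVR(kernel="linear", C=1.0, epsilon=max(eps, 1e-6))
        if self.family == "tree":
            return DecisionTreeRegressor(
                min_samples_leaf=2, random_state=self.random_state
            )
        if self.family == "gp":
            return _exponential_gp(self.random_state)
        raise ModelingError(
            f"unknown stage-2 family {self.family!r}; expected one of {STAGE2_FAMILIES}"
        )

    def _prune_tree(self, tree: DecisionTreeRegressor, X, y) -> DecisionTreeRegressor:
        """Cost-complexity pruning with the alpha chosen by inner 3-fold CV."""
        path = tree.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0, None))
        if alphas.size <= 1 or X.shape[0] < 6:
            return tree
        cv = KFold(n_splits=3, shuffle=True, random_state=self.random_state)
        scores = []
        for a in alphas:
            fold_mse = []
            for tr, te in cv.split(X):
                m = DecisionTreeRegressor(
                    min_samples_leaf=2, ccp_alpha=a, random_state=self.random_state
                ).fit(X[tr], y[tr])
                fold_mse.append(np.mean((m.predict(X[te]) - y[te]) ** 2))
            scores.append(np.mean(fold_mse))
        best = alphas[int(np.argmin(scores))]
        return DecisionTreeRegressor(
            min_samples_leaf=2, ccp_alpha=best, random_state=self.random_state
        )

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.allclose(y, y[0]):
            logger.debug("constant regression target %.3g; predicting the constant", y[0])
            self.constant_ = float(y[0])
            self.pipeline_ = None
            return self
        self.constant_ = None
        model = self._make_model(y)
        selector = LassoSelector(
            task="regress", cap=self.cap, standardize=False,
            random_state=self.random_state,
        )
        if self.family == "tree":
            scaler = StandardScaler().fit(X)
            Xs = scaler.transform(X)
            selector.fit(Xs, y)
            Xsel = selector.transform(Xs)
            model = self._prune_tree(model.fit(Xsel, y), Xsel, y)
        self.pipeline_ = Pipeline(
            [("scale", StandardScaler()), ("select", selector), ("reg", model)]
        )
        self.pipeline_.fit(X, y)
        self.selected_indices_ = np.flatnonzero(selector.support_mask_)
        return self

    def predict(self, X):
        check_is_fitted(self, "constant_")
        X = validate_data(self, X, dtype=float, reset=False)
        if self.constant_ is not None:
            pred = np.full(X.shape[0], self.constant_)
        else:
            pred = self.pipeline_.predict(X)
        pred = np.clip(pred, 0.0, float(self.subscore_range))
        if self.round_to_int:
            pred = np.rint(pred)
        return pred


# ---------------------------------------------------------------------------
# leave-one-out harnesses


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def loo_stage1(
    X,
    groups: Sequence[str],
    family: str = "lda",
    cap: int = DEFAULT_CAP,
    random_state: int | None = None,
) -> list[CVRoundResult]:
    """Leave-one-out HD/control classification, one round per subject.

    Feature selection and standardization are refit inside each round, so
    nothing about the held-out subject leaks into training.
    """
    Xf = _as_frame(X)
    y = np.asarray(groups)
    if Xf.shape[0] != y.size:
        raise ModelingError("X and groups disagree on the number of subjects")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ModelingError("need at least 2 subjects in each of exactly 2 classes")
    results = []
    names = np.asarray(Xf.columns, dtype=object)
    for i in range(Xf.shape[0]):
        tr = np.ones(Xf.shape[0], dtype=bool)
        tr[i] = False
        clf = Stage1Classifier(family=family, cap=cap, random_state=random_state)
        clf.fit(Xf.values[tr], y[tr])
        pred = clf.predict(Xf.values[[i]])[0]
        results.append(
            CVRoundResult(
                held_out_id=str(Xf.index[i]),
                selected_features=tuple(names[clf.selected_indices_]),
                prediction=str(pred),
            )
        )
    return results


def loo_stage2(
    X,
    scores: Sequence[float],
    spec: SubscoreSpec,
    family: str = "gp",
    cap: int = DEFAULT_CAP,
    random_state: int | None = None,
) -> list[CVRoundResult]:
    """Leave-one-out subscore regression over symptomatic subjects."""
    Xf = _as_frame(X)
    y = np.asarray(scores, dtype=float)
    if Xf.shape[0] != y.size:
        raise ModelingError("X and scores disagree on the number of subjects")
    if Xf.shape[0] < 5:
        raise ModelingError("need at least 5 symptomatic subjects for stage 2")
    results = []
    names = np.asarray(Xf.columns, dtype=object)
    for i in range(Xf.shape[0]):
        tr = np.ones(Xf.shape[0], dtype=bool)
        tr[i] = False
        reg = Stage2Regressor(
            family=family,
            subscore_range=spec.range,
            cap=cap,
            random_state=random_state,
        )
        reg.fit(Xf.values[tr], y[tr])
        pred = float(reg.predict(Xf.values[[i]])[0])
        selected = (
            tuple(names[reg.selected_indices_]) if reg.constant_ is None else ()
        )
        results.append(
            CVRoundResult(
                held_out_id=str(Xf.index[i]),
                selected_features=selected,
                prediction=pred,
            )
        )
    return results


class TwoStageScorer(RegressorMixin, BaseEstimator):
    """Classify-then-regress predictor for one subscore.

    Fit takes the full cohort with group labels and the target subscore;
    stage 2 trains on the symptomatic subjects only.  ``predict`` assigns 0
    to subjects classified as controls and the stage-2 regression estimate
    to subjects classified as HD.
    """

    def __init__(
        self,
        stage1_family: str = "lda",
        stage2_family: str = "gp",
        subscore_range: int = 60,
        cap: int = DEFAULT_CAP,
        random_state: int | None = None,
    ):
        self.stage1_family = stage1_family
        self.stage2_family = stage2_family
        self.subscore_range = subscore_range
        self.cap = cap
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ModelingError("TwoStageScorer.fit requires group labels")
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        self.classifier_ = Stage1Classifier(
            family=self.stage1_family, cap=self.cap, random_state=self.random_state
        ).fit(X, groups)
        hd = groups == "hd"
        self.regressor_ = Stage2Regressor(
            family=self.stage2_family,
            subscore_range=self.subscore_range,
            cap=self.cap,
            random_state=self.random_state,
        ).fit(X[hd], y[hd])
        return self

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        X = validate_data(self, X, dtype=float, reset=False)
        cls = self.classifier_.predict(X)
        reg = self.regressor_.predict(X)
        return np.where(cls == "hd", reg, 0.0)


def two_stage_predict(
    X,
    groups: Sequence[str],
    scores: Mapping[str, float],
    spec: SubscoreSpec,
    stage1_family: str = "lda",
    stage2_family: str = "gp",
    cap: int = DEFAULT_CAP,
    random_state: int | None = None,
) -> tuple[pd.Series, list[CVRoundResult], list[CVRoundResult]]:
    """Leave-one-out two-stage score prediction for every subject.

    ``scores`` maps symptomatic subject ids to the true subscore.  Subjects
    LOO-classified as controls get 0; subjects LOO-classified as HD get a
    stage-2 prediction — the LOO one for true HD subjects, and a prediction
    from a model trained on all HD subjects for misclassified controls
    (whose own data never enters stage-2 training).
    """
    Xf = _as_frame(X)
    groups = np.asarray(groups)
    s1 = loo_stage1(Xf, groups, stage1_family, cap, random_state)
    predicted_class = {r.held_out_id: r.prediction for r in s1}

    hd_ids = [str(i) for i, g in zip(Xf.index, groups) if g == "hd"]
    X_hd = Xf.loc[hd_ids]
    y_hd = np.array([scores[i] for i in hd_ids], dtype=float)
    s2 = loo_stage2(X_hd, y_hd, spec, stage2_family, cap, random_state)
    loo_pred_hd = {r.held_out_id: float(r.prediction) for r in s2}

    full_reg = Stage2Regressor(
        family=stage2_family,
        subscore_range=spec.range,
        cap=cap,
        random_state=random_state,
    ).fit(X_hd.values, y_hd)

    out = {}
    for i, (sid, g) in enumerate(zip(Xf.index, groups)):
        sid = str(sid)
        if predicted_class[sid] == "control":
            out[sid] = 0.0
        elif g == "hd":
            out[sid] = loo_pred_hd[sid]
        else:  # control misclassified as HD: score it with the full HD model
            out[sid] = float(full_reg.predict(Xf.values[[i]])[0])
    return pd.Series(out, name=spec.name), s1, s2


def composite_strategies(
    X,
    scores: pd.DataFrame,
    stage2_family: str = "gp",
    cap: int = DEFAULT_CAP,
    random_state: int | None = None,
) -> pd.DataFrame:
    """Two ways to predict the composite subscore over symptomatic subjects.

    ``summed``: LOO-predict each of the seven subscores independently and
    add the predictions.  ``direct``: LOO-train a single model on the
    composite (range 60).  Returns one row per subject with both.
    """
    Xf = _as_frame(X)
    missing = [n for n in SUBSCORE_SPECS if n != "composite" and n not in scores]
    if missing:
        raise ModelingError(f"scores table missing subscores: {missing}")
    summed = np.zeros(Xf.shape[0])
    for name, spec in SUBSCORE_SPECS.items():
        if name == "composite":
            continue
        res = loo_stage2(
            Xf, scores[name].to_numpy(float), spec, stage2_family, cap, random_state
        )
        summed += np.array([float(r.prediction) for r in res])
    composite = scores[list(n for n in SUBSCORE_SPECS if n != "composite")].sum(axis=1)
    res = loo_stage2(
        Xf, composite.to_numpy(float), SUBSCORE_SPECS["composite"],
        stage2_family, cap, random_state,
    )
    direct = np.array([float(r.prediction) for r in res])
    return pd.DataFrame(
        {"summed": summed, "direct": direct, "true_composite": composite.to_numpy(float)},
        index=Xf.index,
    )
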