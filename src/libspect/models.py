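"""Constituent classifiers used as sub-models and baselines.

Three lightweight classifiers cover the usual chemometric repertoire: an
RBF-kernel support vector machine, a random forest, and k-nearest
neighbours. Distance-based models (SVM, KNN) are wrapped with per-channel
standardization, fitted on training data only; the forest is scale-free.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: Default hyperparameters; chemometrics-conventional, not tuned per dataset.
DEFAULTS = {
    "svm": {"C": 10.0, "gamma": "scale"},
    "rf": {"n_estimators": 200, "max_depth": None},
    "knn": {"n_neighbors": 5},
}

#: Small per-model grids for optional validation-accuracy tuning.
PARAM_GRIDS = {
    "svm": [{"C": c, "gamma": g} for c in (1.0, 10.0, 100.0) for g in ("scale", 0.01)],
    "rf": [
        {"n_estimators": n, "max_depth": d} for n in (100, 200) for d in (None, 20)
    ],
    "knn": [{"n_neighbors": k} for k in (1, 3, 5, 9)],
}


def make_classifier(
    spec: str | BaseEstimator,
    random_state: int | None = None,
    **overrides,
) -> BaseEstimator:
    """Build one classifier from a short name ("svm", "rf", "knn") or clone a
    given estimator."""
    if not isinstance(spec, str):
        return clone(spec)
    params = dict(DEFAULTS.get(spec, {}), **overrides)
    if spec == "svm":
        return make_pipeline(StandardScaler(), SVC(random_state=random_state, **params))
    if spec == "rf":
        return RandomForestClassifier(random_state=random_state, **params)
    if spec == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**params))
    raise ValueError(f"unknown classifier spec {spec!r}; expected svm, rf or knn")


def set_model_params(estimator: BaseEstimator, params: dict) -> BaseEstimator:
    """Apply a flat hyperparameter dict to a classifier or its final pipeline
    step."""
    est = clone(estimator)
    if isinstance(est, Pipeline):
        est.steps[-1][1].set_params(**params)
    else:
        est.set_params(**params)
    return est
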