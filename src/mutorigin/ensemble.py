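"""One-vs-rest random-forest ensemble for primary-site classification.

One binary forest is trained per primary site (site vs rest). Each of
its trees is grown on a stratified bootstrap: m cases and m non-cases
drawn with replacement, where m = round(0.632 x the size of the smaller
group), so every tree sees balanced classes. Trees consider floor(sqrt(p))
candidate features per split, with p the total feature count.

The *classification score* for a site is the proportion of that site's
trees voting "this site"; scores are independent across sites and need
not sum to one. A sample is assigned the highest-scoring site, and the
*confidence score* is the difference between the two highest site
scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix

__all__ = [
    "SiteVoteForest",
    "ClassificationResult",
    "train_ensemble",
    "score_sample",
    "classify",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class ClassificationResult:
    """Ranked site scores for one sample.

    ``confidence`` is score(rank 1) minus score(rank 2); ties at the top
    are broken by site order, giving confidence 0.
    """

    sample_id: str
    scores: dict[str, float]
    predicted_site: str
    confidence: float
    ranked_sites: list[tuple[str, float]] = field(default_factory=list)


class SiteVoteForest(ClassifierMixin, BaseEstimator):
    """One-vs-rest ensemble of stratified-bootstrap random forests.

    Parameters
    ----------
    n_trees : int, default 500
        Trees per binary (site vs rest) forest.
    strat_fraction : float, default 0.632
        Per-tree sample size as a fraction of the smaller stratum;
        that many samples are drawn with replacement from cases and
        from non-cases alike.
    random_state : int, default 0
        Master seed; per-site sub-seeds are derived from it and the
        site's index, so a site's forest does not depend on which other
        sites are present later in the order.
    site_order : sequence of str, optional
        Explicit class order (defines score-tie breaking); defaults to
        lexicographic order of the observed labels.

    Attributes
    ----------
    classes_ : ndarray of site labels in site order
    estimators_ : dict site -> list of fitted trees
    feature_names_in_ : list of str (when fit on a DataFrame)
    training_counts_ : dict site -> number of training samples
    mtry_ : int, candidate features per split
    """

    def __init__(
        self,
        n_trees: int = 500,
        strat_fraction: float = 0.632,
        random_state: int = 0,
        site_order: list[str] | None = None,
    ):
        self.n_trees = n_trees
        self.strat_fraction = strat_fraction
        self.random_state = random_state
        self.site_order = site_order

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "SiteVoteForest":
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.strat_fraction <= 1:
            raise ValueError("strat_fraction must be in (0, 1]")
        Xarr, names = _as_array(X)
        if np.isnan(Xarr).any():
            raise ValueError("feature matrix contains missing values")
        y = np.asarray(y, dtype=object)
        if len(y) != Xarr.shape[0]:
            raise ValueError("X and y length mismatch")
        sites = sorted(set(y)) if self.site_order is None else list(self.site_order)
        if set(y) - set(sites):
            raise ValueError(f"labels outside site_order: {sorted(set(y) - set(sites))}")
        if len(sites) < 2:
            raise ValueError("at least two sites are required")
        counts = {s: int(np.sum(y == s)) for s in sites}
        for s, n in counts.items():
            if n < 2:
                raise ValueError(f"site {s!r} has fewer than 2 samples")

        p = Xarr.shape[1]
        self.mtry_ = max(1, math.floor(math.sqrt(p)))
        self.n_features_in_ = p
        if names is not None:
            self.feature_names_in_ = names
        self.classes_ = np.asarray(sites, dtype=object)
        self.training_counts_ = counts
        self.estimators_ = {}
        for site_idx, site in enumerate(sites):
            self.estimators_[site] = self._fit_site(Xarr, y, site, site_idx)
        return self

    def _fit_site(self, X, y, site, site_idx) -> list[DecisionTreeClassifier]:
        rng = np.random.default_rng(
            np.random.SeedSequence(self.random_state, spawn_key=(site_idx,))
        )
        cases = np.flatnonzero(y == site)
        noncases = np.flatnonzero(y != site)
        m = max(1, round(self.strat_fraction * min(len(cases), len(noncases))))
        trees = []
        for _ in range(self.n_trees):
            idx = np.concatenate(
                [rng.choice(cases, size=m, replace=True),
                 rng.choice(noncases, size=m, replace=True)]
            )
            ytree = (y[idx] == site).astype(int)
            tree = DecisionTreeClassifier(
                max_features=self.mtry_,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], ytree)
            trees.append(tree)
        return trees

    # ------------------------------------------------------------------
    def predict_scores(self, X) -> pd.DataFrame:
        """Per-site classification scores (vote proportions), one column
        per site in site order. Rows are independent binary scores and
        do not sum to 1."""
        check_is_fitted(self, "estimators_")
        Xarr, names = _as_array(X)
        if names is not None and hasattr(self, "feature_names_in_"):
            if names != self.feature_names_in_:
                raise ValueError(
                    "feature names do not match the training-time contract"
                )
        elif Xarr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {Xarr.shape[1]}"
            )
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xarr))
        scores = np.zeros((Xarr.shape[0], len(self.classes_)))
        for j, site in enumerate(self.classes_):
            votes = np.zeros(Xarr.shape[0])
            for tree in self.estimators_[site]:
                votes += tree.predict(Xarr)
            scores[:, j] = votes / self.n_trees
        return pd.DataFrame(scores, index=index, columns=list(self.classes_))

    def predict(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        # argmax takes the first maximum, i.e. ties break by site order
        return self.classes_[np.argmax(scores.to_numpy(), axis=1)]

    def classify_samples(self, X) -> list[ClassificationResult]:
        """Full ranked output with confidence scores."""
        check_is_fitted(self, "estimators_")
        if len(self.classes_) < 2:
            raise ValueError("classification requires at least two trained sites")
        scores = self.predict_scores(X)
        results = []
        for sample_id, row in scores.iterrows():
            ranked = sorted(
                row.items(), key=lambda kv: (-kv[1], list(self.classes_).index(kv[0]))
            )
            confidence = ranked[0][1] - ranked[1][1]
            results.append(
                ClassificationResult(
                    sample_id=str(sample_id),
                    scores=dict(row),
                    predicted_site=ranked[0][0],
                    confidence=float(confidence),
                    ranked_sites=[(s, float(v)) for s, v in ranked],
                )
            )
        return results


def _as_array(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, FeatureMatrix):
        X = X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def train_ensemble(
    fm: FeatureMatrix,
    n_trees: int = 500,
    strat_fraction: float = 0.632,
    random_state: int = 0,
    site_order: list[str] | None = None,
) -> SiteVoteForest:
    """Train the one-vs-rest ensemble from a labelled feature matrix."""
    if fm.site_labels is None:
        raise ValueError("feature matrix has no site labels")
    model = SiteVoteForest(
        n_trees=n_trees,
        strat_fraction=strat_fraction,
        random_state=random_state,
        site_order=site_order,
    )
    return model.fit(fm.values, fm.site_labels.to_numpy())


def score_sample(model: SiteVoteForest, x) -> dict[str, float]:
    row = _one_row(x)
    scores = model.predict_scores(row)
    return dict(scores.iloc[0])


def classify(model: SiteVoteForest, x) -> ClassificationResult:
    return model.classify_samples(_one_row(x))[0]


def _one_row(x) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    if isinstance(x, pd.Series):
        return x.to_frame().T
    return pd.DataFrame(np.atleast_2d(np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: SiteVoteForest, path) -> None:
    check_is_fitted(model, "estimators_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "state": {
            "classes_": model.classes_,
            "estimators_": model.estimators_,
            "training_counts_": model.training_counts_,
            "mtry_": model.mtry_,
            "n_features_in_": model.n_features_in_,
            "feature_names_in_": getattr(model, "feature_names_in_", None),
        },
    }
    joblib.dump(payload, path)


def load_model(path) -> SiteVoteForest:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated/corrupt file
        raise ValueError(f"could not read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a recognized model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} is not "
            f"supported (expected {MODEL_FORMAT_VERSION})"
        )
    model = SiteVoteForest(**payload["params"])
    for attr, value in payload["state"].items():
        if value is not None or attr != "feature_names_in_":
            setattr(model, attr, value)
    return model
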