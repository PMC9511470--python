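"""scikit-learn style estimators over the library surface.

``EpsOptExtractor`` turns a matrix of fixed-length segments into their
eps_opt values (a stateless transformer, so it composes with sklearn
pipelines and model selection); ``IhhopClassifier`` learns the Jenks
three-region boundaries from a corpus of eps_opt values and assigns the
no / maybe / with classes; ``SasScreener`` is a fitted screening
classifier (z-scoring plus AdaBoost, LDA or random forest).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .classification import IhhopThresholds, classify_ihhop, ihhop_thresholds_from_corpus, make_classifier
from .io import OximetryRecord
from .preprocess import preprocess
from .recurrence import segment_eps_opt

__all__ = ["EpsOptExtractor", "IhhopClassifier", "SasScreener"]


class EpsOptExtractor(TransformerMixin, BaseEstimator):
    """Transform rows of SaO2 samples into eps_opt values.

    Each row of X is one fixed-length segment sampled at ``fs``; the
    output is a single-column matrix of optimal recurrence thresholds.

    Parameters
    ----------
    fs : sampling frequency of the segments, Hz.
    l_min : minimal diagonal line length, or 'auto' (10 samples at 1 Hz,
        2 at 0.1 Hz).
    grid_points : threshold-grid resolution for the DET curve.
    preprocess : apply the clip + zero-phase low-pass chain per row
        before the recurrence analysis.
    """

    def __init__(
        self,
        fs: float = 1.0,
        l_min="auto",
        grid_points: int = 100,
        theiler: int = 1,
        preprocess: bool = True,
    ):
        self.fs = fs
        self.l_min = l_min
        self.grid_points = grid_points
        self.theiler = theiler
        self.preprocess = preprocess

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            x = row
            if self.preprocess:
                x = preprocess(OximetryRecord.from_values(row, fs=self.fs)).values
            out[i] = segment_eps_opt(
                x,
                l_min=self.l_min,
                fs=self.fs,
                grid_points=self.grid_points,
                theiler=self.theiler,
            ).value
        return out[:, None]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["eps_opt"], dtype=object)


class IhhopClassifier(ClassifierMixin, BaseEstimator):
    """Three-region IHHOP classing of eps_opt values.

    With ``thresholds='jenks'`` (default) the two boundaries are learned
    from the values seen in ``fit`` via exact Jenks natural breaks; a
    (t_low, t_high) tuple fixes them instead (e.g. the reference
    0.33 / 0.73 obtained on 5-min 1 Hz segments).
    """

    def __init__(self, thresholds="jenks"):
        self.thresholds = thresholds

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False)
        values = np.ravel(X)
        if self.thresholds == "jenks":
            thr = ihhop_thresholds_from_corpus(values)
        else:
            thr = IhhopThresholds(*self.thresholds)
        self.t_low_ = thr.t_low
        self.t_high_ = thr.t_high
        self.classes_ = np.asarray(["maybe", "no", "with"], dtype=object)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=False)
        thr = IhhopThresholds(self.t_low_, self.t_high_)
        return np.asarray([classify_ihhop(v, thr) for v in np.ravel(X)], dtype=object)


class SasScreener(ClassifierMixin, BaseEstimator):
    """Binary SAS screening from eps_opt features.

    A thin sklearn wrapper around z-scored features feeding one of the
    three study classifiers ('adaboost', 'lda', 'random_forest').
    """

    def __init__(self, algo: str = "lda", random_state: int = 0):
        self.algo = algo
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X)
        self.pipeline_ = make_classifier(self.algo, random_state=self.random_state)
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.pipeline_.predict(check_array(X))

    def predict_proba(self, X):
        check_is_fitted(self)
        return self.pipeline_.predict_proba(check_array(X))
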