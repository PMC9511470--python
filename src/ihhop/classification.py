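"""IHHOP classing, SAS labels and the binary-screening harness.

Per-segment eps_opt values fall into three natural regions — "no",
"maybe" and "with" IHHOP — whose boundaries are found with Jenks natural
breaks (exact dynamic-programming minimisation of within-class squared
deviation); the defaults 0.33 / 0.73 SaO2 percentage points are the
boundaries obtained on intradialytic 5-min segments at 1 Hz with
l_min = 10 and should be re-derived for other geometries.

Severity labels come from the desaturation density: the trailing 10-min
event count is converted to an hourly rate (x6) and cut at the
ASDS apnea-hypopnea thresholds 5 / 15 / 30 events per hour (healthy /
mild / moderate / severe, boundaries to the higher class).  Three
binarisation schemes (>Mild, >Moderate, >Severe) turn severities into
with/without-SAS labels, which the screening harness predicts from
eps_opt with AdaBoost, LDA and random-forest classifiers on a 70/30
stratified split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "IhhopThresholds",
    "SegmentLabel",
    "RocResult",
    "IHHOP_CLASSES",
    "SAS_CLASSES",
    "SCHEMES",
    "jenks_breaks",
    "ihhop_thresholds_from_corpus",
    "classify_ihhop",
    "sas_class_from_odd",
    "binarize",
    "confusion_metrics",
    "make_classifier",
    "evaluate_classifiers",
]

IHHOP_CLASSES = ("no", "maybe", "with")
SAS_CLASSES = ("healthy", "mild", "moderate", "severe")
SCHEMES = (">Mild", ">Moderate", ">Severe")

#: hourly AHI-style cut-offs (events/h) between healthy/mild/moderate/severe
ASDS_CUTOFFS = (5.0, 15.0, 30.0)

#: a 10-min trailing count times 6 is an hourly rate
ODD_TO_HOURLY = 6.0


@dataclass
class IhhopThresholds:
    """Boundaries of the no / maybe / with IHHOP regions (signal units)."""

    t_low: float = 0.33
    t_high: float = 0.73

    def __post_init__(self) -> None:
        if not 0 < self.t_low < self.t_high:
            raise ValueError("need 0 < t_low < t_high")


@dataclass
class SegmentLabel:
    """Everything the pipeline knows about one analysed segment."""

    segment_id: int
    eps_opt: float
    ihhop_class: str
    odd_count: int
    sas_class: str
    binary: dict[str, str] = field(default_factory=dict)  # scheme -> with/without


@dataclass
class RocResult:
    classifier: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    op_threshold: float
    op_tpr: float
    op_fpr: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    seed: int


def jenks_breaks(values, k: int = 3) -> np.ndarray:
    """Exact Jenks natural breaks for one-dimensional data.

    Finds the contiguous k-partition of the sorted values minimising the
    total within-class sum of squared deviations, by O(k n^2) dynamic
    programming with a numpy-vectorised inner loop (exact for any n that
    fits in memory; at n ~ 1e4 the table costs a few seconds).  Returns
    the k - 1 break values, each the midpoint between the largest value
    of one class and the smallest value of the next.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(v).size < k:
        raise ValueError("need at least k distinct values")
    if k == 1:
        return np.array([])
    s1 = np.concatenate(([0.0], np.cumsum(v)))
    s2 = np.concatenate(([0.0], np.cumsum(v * v)))

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-class SSE of v[i:j] for a vector of candidate i
        cnt = j - i
        su = s1[j] - s1[i]
        return (s2[j] - s2[i]) - su * su / cnt

    INF = np.inf
    cost = np.full((k, n + 1), INF)
    back = np.zeros((k, n + 1), dtype=int)
    idx_all = np.arange(n + 1)
    cost[0, 1:] = [seg_cost(np.array([0]), j)[0] for j in range(1, n + 1)]
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            i = idx_all[c:j]  # previous boundary candidates
            tot = cost[c - 1, c:j] + seg_cost(i, j)
            a = int(np.argmin(tot))
            cost[c, j] = tot[a]
            back[c, j] = i[a]
    # recover boundary indices
    bounds = []
    j = n
    for c in range(k - 1, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds.reverse()
    return np.array([(v[b - 1] + v[b]) / 2.0 for b in bounds])


def ihhop_thresholds_from_corpus(eps_values) -> IhhopThresholds:
    """Re-derive the three-region boundaries from a corpus of eps_opt values."""
    lo, hi = jenks_breaks(eps_values, k=3)
    return IhhopThresholds(t_low=float(lo), t_high=float(hi))


def classify_ihhop(eps_opt: float, thr: IhhopThresholds | None = None) -> str:
    """'no' below t_low, 'maybe' in [t_low, t_high), 'with' at or above t_high."""
    if eps_opt < 0:
        raise ValueError("eps_opt must be nonnegative")
    thr = thr or IhhopThresholds()
    if eps_opt < thr.t_low:
        return "no"
    if eps_opt < thr.t_high:
        return "maybe"
    return "with"


def sas_class_from_odd(odd_count: float) -> str:
    """Severity from a trailing-10-min desaturation count.

    The count is scaled to an hourly rate and cut at 5 / 15 / 30 events
    per hour; a rate exactly on a cut-off goes to the higher class.
    """
    if odd_count < 0:
        raise ValueError("odd_count must be nonnegative")
    hourly = odd_count * ODD_TO_HOURLY
    if hourly < ASDS_CUTOFFS[0]:
        return "healthy"
    if hourly < ASDS_CUTOFFS[1]:
        return "mild"
    if hourly < ASDS_CUTOFFS[2]:
        return "moderate"
    return "severe"


def binarize(sas_class: str, scheme: str = ">Mild") -> str:
    """'with_sas' / 'without_sas' under one of the three schemes."""
    if sas_class not in SAS_CLASSES:
        raise ValueError(f"unknown class {sas_class!r}")
    positive = {
        ">Mild": {"mild", "moderate", "severe"},
        ">Moderate": {"moderate", "severe"},
        ">Severe": {"severe"},
    }
    if scheme not in positive:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    return "with_sas" if sas_class in positive[scheme] else "without_sas"


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV and NPV from confusion counts."""
    def safe(a, b):
        return a / b if b else float("nan")

    return {
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
    }


def make_classifier(algo: str, random_state: int = 0) -> Pipeline:
    """Feature z-scoring plus one of the three screening classifiers."""
    models = {
        "adaboost": lambda: AdaBoostClassifier(random_state=random_state),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "random_forest": lambda: RandomForestClassifier(random_state=random_state),
    }
    if algo not in models:
        raise ValueError(f"unknown algorithm {algo!r}; one of {sorted(models)}")
    return Pipeline([("scale", StandardScaler()), ("model", models[algo]())])


def evaluate_classifiers(
    features,
    labels,
    algos: tuple[str, ...] = ("adaboost", "lda", "random_forest"),
    test_size: float = 0.3,
    seed: int = 0,
    pos_label="with_sas",
) -> list[RocResult]:
    """Fit each screening classifier and score it on a held-out split.

    Features are z-scored on the training split only; the ROC operating
    point is the curve point farthest (Euclidean) from (FPR=1, TPR=0),
    and sensitivity / specificity / PPV / NPV are reported there.
    Segments, not patients, are the unit of classification, so segments
    of one recording may land in both splits.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray([lab == pos_label if isinstance(lab, str) else bool(lab) for lab in labels])
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if y.size < 20:
        raise ValueError("need at least 20 segments")
    if np.ptp(X, axis=0).min() == 0:
        raise ValueError("degenerate feature with zero variance")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    results = []
    for algo in algos:
        clf = make_classifier(algo, random_state=seed).fit(X_tr, y_tr)
        scores = clf.predict_proba(X_te)[:, list(clf.classes_).index(True)]
        fpr, tpr, thr = roc_curve(y_te, scores)
        dist = np.hypot(fpr - 1.0, tpr)
        i = int(np.argmax(dist))
        pred = scores >= thr[i]
        tp = int(np.sum(pred & y_te))
        fn = int(np.sum(~pred & y_te))
        tn = int(np.sum(~pred & ~y_te))
        fp = int(np.sum(pred & ~y_te))
        m = confusion_metrics(tp, fn, tn, fp)
        results.append(
            RocResult(
                classifier=algo,
                fpr=fpr,
                tpr=tpr,
                thresholds=thr,
                auc=float(_auc(fpr, tpr)),
                op_threshold=float(thr[i]),
                op_tpr=float(tpr[i]),
                op_fpr=float(fpr[i]),
                sensitivity=m["sensitivity"],
                specificity=m["specificity"],
                ppv=m["ppv"],
                npv=m["npv"],
                seed=seed,
            )
        )
    return results
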