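import itertools

import numpy as np
import pytest

from ihhop import (
    IhhopThresholds,
    binarize,
    classify_ihhop,
    confusion_metrics,
    evaluate_classifiers,
    ihhop_thresholds_from_corpus,
    jenks_breaks,
    sas_class_from_odd,
)


def brute_jenks_sse(values, k):
    """Exhaustive search over all contiguous k-partitions of the sorted data."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        total = sum(sse(v[a:b]) for a, b in zip(bounds, bounds[1:]))
        if total < best[0] - 1e-12:
            best = (total, cuts)
    return best


class TestJenksBreaks:
    def test_perfectly_separated_clusters(self):
        breaks = jenks_breaks([1, 1, 1, 5, 5, 5, 10, 10, 10], k=3)
        assert 1 < breaks[0] < 5 < breaks[1] < 10

    def test_k_one_no_breaks(self):
        assert jenks_breaks([1.0, 2.0, 3.0], k=1).size == 0

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 1.0, 2.0], k=3)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_search(self, rng, k):
        for n in (12, 30, 60):
            v = np.sort(rng.normal(0.0, 1.0, n))
            best_sse, cuts = brute_jenks_sse(v, k)
            breaks = jenks_breaks(v, k=k)
            # rebuild the DP partition's SSE from its breaks
            labels = np.searchsorted(breaks, v, side="right")
            got = sum(
                float(np.sum((v[labels == c] - v[labels == c].mean()) ** 2))
                for c in range(k)
            )
            assert got == pytest.approx(best_sse, abs=1e-9)

    def test_mixture_midpoint_recovery(self):
        r = np.random.default_rng(99)
        v = np.concatenate(
            [r.normal(m, 0.03, 67) for m in (0.2, 0.5, 0.9)]
        )[:200]
        breaks = jenks_breaks(v, k=3)
        assert breaks[0] == pytest.approx(0.35, abs=0.05)
        assert breaks[1] == pytest.approx(0.70, abs=0.05)


class TestIhhopClassing:
    @pytest.mark.parametrize(
        "eps,expected", [(0.10, "no"), (0.50, "maybe"), (0.90, "with"),
                         (0.33, "maybe"), (0.73, "with")]
    )
    def test_default_boundaries(self, eps, expected):
        assert classify_ihhop(eps) == expected

    def test_monotone_in_eps(self, rng):
        thr = IhhopThresholds(0.4, 0.8)
        order = {"no": 0, "maybe": 1, "with": 2}
        vals = np.sort(rng.uniform(0, 2, 50))
        ranks = [order[classify_ihhop(v, thr)] for v in vals]
        assert ranks == sorted(ranks)

    def test_thresholds_from_corpus(self, rng):
        v = np.concatenate(
            [rng.normal(0.2, 0.03, 80), rng.normal(0.6, 0.05, 40), rng.normal(1.2, 0.1, 30)]
        )
        thr = ihhop_thresholds_from_corpus(np.abs(v))
        assert 0.2 < thr.t_low < 0.6 < thr.t_high < 1.2


class TestSasLabels:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "healthy"), (1, "mild"), (2, "mild"), (3, "moderate"),
         (4, "moderate"), (5, "severe"), (6, "severe")],
    )
    def test_hourly_conversion_and_cutoffs(self, count, expected):
        assert sas_class_from_odd(count) == expected

    def test_boundary_goes_to_higher_class(self):
        # 5/6 of an event per 10 min is exactly 5/h -> mild, not healthy
        assert sas_class_from_odd(5 / 6) == "mild"

    @pytest.mark.parametrize(
        "cls,scheme,expected",
        [
            ("mild", ">Mild", "with_sas"),
            ("mild", ">Moderate", "without_sas"),
            ("moderate", ">Moderate", "with_sas"),
            ("moderate", ">Severe", "without_sas"),
            ("severe", ">Severe", "with_sas"),
            ("healthy", ">Mild", "without_sas"),
        ],
    )
    def test_binarize_schemes(self, cls, scheme, expected):
        assert binarize(cls, scheme) == expected

    def test_positive_sets_nest(self):
        pos = {
            s: {c for c in ("healthy", "mild", "moderate", "severe") if binarize(c, s) == "with_sas"}
            for s in (">Mild", ">Moderate", ">Severe")
        }
        assert pos[">Severe"] <= pos[">Moderate"] <= pos[">Mild"]


class TestConfusionMetrics:
    def test_printed_counts(self):
        m = confusion_metrics(tp=9, fn=1, tn=8, fp=2)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)

    def test_ppv_falls_with_prevalence(self):
        # fixed sens/spec, decreasing positive prevalence -> PPV decreases
        sens, spec = 0.9, 0.8
        ppvs = []
        for n_pos in (500, 200, 50):
            n_neg = 1000 - n_pos
            tp = int(sens * n_pos)
            fn = n_pos - tp
            tn = int(spec * n_neg)
            fp = n_neg - tn
            ppvs.append(confusion_metrics(tp, fn, tn, fp)["ppv"])
        assert ppvs == sorted(ppvs, reverse=True)


class TestEvaluateClassifiers:
    def test_perfectly_separable_feature(self, rng):
        feats = np.concatenate(
            [rng.normal(1.0, 0.01, 30), rng.normal(0.1, 0.01, 30)]
        )
        y = ["with_sas"] * 30 + ["without_sas"] * 30
        for res in evaluate_classifiers(feats, y, seed=0):
            assert res.auc == pytest.approx(1.0)
            assert res.sensitivity == pytest.approx(1.0)
            assert res.specificity == pytest.approx(1.0)

    def test_permuted_labels_are_chance(self):
        r = np.random.default_rng(7)
        feats = r.normal(size=200)
        y = r.permutation(["with_sas"] * 100 + ["without_sas"] * 100)
        for res in evaluate_classifiers(feats, list(y), algos=("lda",), seed=7):
            assert res.auc == pytest.approx(0.5, abs=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifiers(np.arange(30.0), ["with_sas"] * 30, seed=0)

    def test_zero_variance_feature_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifiers(
                np.ones(30), ["with_sas"] * 15 + ["without_sas"] * 15, seed=0
            )

    def test_operating_point_on_curve(self, rng):
        feats = np.concatenate([rng.normal(1, 0.5, 60), rng.normal(0, 0.5, 60)])
        y = ["with_sas"] * 60 + ["without_sas"] * 60
        for res in evaluate_classifiers(feats, y, seed=3):
            i = int(np.argmin(np.abs(res.thresholds - res.op_threshold)))
            assert res.tpr[i] == pytest.approx(res.op_tpr)
            assert res.fpr[i] == pytest.approx(res.op_fpr)
            assert 0.0 <= res.auc <= 1.0
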