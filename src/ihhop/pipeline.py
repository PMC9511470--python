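"""End-to-end glue: record -> preprocessed segment -> eps_opt + SAS label.

These helpers tie the preprocessing, recurrence, desaturation and
classification stages together for corpus-level work (screening studies,
the CLI, simulations); each stage remains individually usable.
"""

from __future__ import annotations

import numpy as np

from .classification import RocResult, SegmentLabel, binarize, classify_ihhop, evaluate_classifiers, sas_class_from_odd, IhhopThresholds
from .desaturation import compute_baseline, detect_desaturations, odd_series
from .io import OximetryRecord
from .preprocess import preprocess
from .recurrence import segment_eps_opt
from .rolling import rolling_eps_opt

__all__ = ["label_segment", "screen_corpus", "eps_opt_vs_odd"]


def label_segment(
    record: OximetryRecord,
    segment_id: int = 0,
    n_pct: float = 3.0,
    thresholds: IhhopThresholds | None = None,
    floor: float = 75.0,
    cutoff: float = 0.25,
) -> SegmentLabel:
    """Analyse one standalone segment (typically 5 min at 1 Hz).

    The segment is preprocessed (clip + zero-phase low-pass), eps_opt is
    computed over the whole segment, desaturations are detected against
    the segment's own first-3-min baseline, and the event count (the
    trailing-window density at segment end) is converted to a severity
    class and its three binarisations.
    """
    pp = preprocess(record, floor=floor, cutoff=cutoff)
    est = segment_eps_opt(pp.values, l_min="auto", fs=pp.fs)
    baseline = compute_baseline(pp)
    events = detect_desaturations(pp, baseline, n_pct=n_pct)
    odd_count = len(events)
    sas = sas_class_from_odd(odd_count)
    return SegmentLabel(
        segment_id=segment_id,
        eps_opt=est.value,
        ihhop_class=classify_ihhop(est.value, thresholds),
        odd_count=odd_count,
        sas_class=sas,
        binary={s: binarize(sas, s) for s in (">Mild", ">Moderate", ">Severe")},
    )


def screen_corpus(
    records: list[OximetryRecord],
    scheme: str = ">Mild",
    seed: int = 0,
    n_pct: float = 3.0,
) -> tuple[list[SegmentLabel], list[RocResult]]:
    """Label every segment and run the three screening classifiers.

    Returns the per-segment labels and one RocResult per classifier
    (eps_opt is the single feature; 70/30 stratified split).
    """
    labels = [label_segment(r, segment_id=i, n_pct=n_pct) for i, r in enumerate(records)]
    feats = np.array([lab.eps_opt for lab in labels])
    y = [lab.binary[scheme] for lab in labels]
    results = evaluate_classifiers(feats, y, seed=seed)
    return labels, results


def eps_opt_vs_odd(
    record: OximetryRecord,
    window_s: float = 600.0,
    step_s: float = 60.0,
    n_pct: float = 3.0,
    floor: float = 75.0,
    cutoff: float = 0.25,
):
    """Rolling eps_opt and the ODD evaluated on the same window-end grid.

    Returns (eps_series, odd) so the two metrics can be compared point
    for point: the eps_opt of window [t - W, t] against the count of
    desaturations timestamped in (t - W, t].
    """
    pp = preprocess(record, floor=floor, cutoff=cutoff)
    eps = rolling_eps_opt(pp, window_s=window_s, step_s=step_s)
    baseline = compute_baseline(pp)
    events = detect_desaturations(pp, baseline, n_pct=n_pct)
    odd = odd_series(events, eps.window_ends, lookback_s=window_s)
    return eps, odd
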