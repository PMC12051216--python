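"""Horizon risk prediction protocol: balanced down-sampling, stratified
80/20 split, NHPP event probabilities, threshold classification, ROC/AUC.

Risk over a horizon h starting at s is the NHPP no-event probability
complement, p = 1 - exp(-(Lambda(s+h|x) - Lambda(s|x))).  Class
imbalance is handled by keeping every case and sampling an equal
number of controls without replacement before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nhpp import NHPPParams, cumulative_intensity

#: prediction horizons in weeks: six months, one year, two years
HORIZONS = (26.0, 52.0, 104.0)


@dataclass
class HorizonPrediction:
    subject_id: str
    start_time: float    # weeks; first date with complete covariates
    horizon: float       # weeks
    probability: float
    observed_label: bool


def downsample_balance(cohort_labels: dict[str, bool], seed: int = 0) -> list[str]:
    """Keep all cases; sample an equal number of controls uniformly.

    ``cohort_labels`` maps subject_id to case status.  Returns the
    balanced subject list (cases then sampled controls).
    """
    cases = [s for s, y in cohort_labels.items() if y]
    controls = [s for s, y in cohort_labels.items() if not y]
    if len(cases) < 1:
        raise ValueError("need at least one case")
    if len(controls) < len(cases):
        raise ValueError(
            f"{len(controls)} controls < {len(cases)} cases: cannot down-sample"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(controls), size=len(cases), replace=False)
    return cases + [controls[i] for i in sorted(picked)]


def stratified_split(
    balanced_labels: dict[str, bool], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Per-group split: floor(train_frac * n_group) to train, rest to test."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for value in (True, False):
        group = [s for s, y in balanced_labels.items() if y is bool(value)]
        if not group:
            raise ValueError(f"group {value} is empty")
        n_train = int(np.floor(train_frac * len(group)))
        perm = rng.permutation(len(group))
        train += [group[i] for i in perm[:n_train]]
        test += [group[i] for i in perm[n_train:]]
    return train, test


def event_probability(nhpp_fit_or_params, x, s: float, h: float) -> float:
    """P(>= 1 event in (s, s+h] | x) under the fitted NHPP."""
    if s < 0 or h <= 0:
        raise ValueError("require s >= 0 and h > 0")
    params = getattr(nhpp_fit_or_params, "params", nhpp_fit_or_params)
    assert isinstance(params, NHPPParams)
    gap = cumulative_intensity(s + h, x, params) - cumulative_intensity(s, x, params)
    return float(1.0 - np.exp(-gap))


def classify(predictions: list[HorizonPrediction], threshold: float) -> dict:
    """Threshold rule (positive iff p > threshold) with confusion counts."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    p = np.array([pr.probability for pr in predictions])
    y = np.array([pr.observed_label for pr in predictions], dtype=bool)
    pred = p > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    npos, nneg = tp + fn, tn + fp
    return {
        "labels": pred,
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "sensitivity": tp / npos if npos else np.nan,
        "specificity": tn / nneg if nneg else np.nan,
        "FNR": fn / npos if npos else np.nan,
    }


def roc_auc(labels, probabilities) -> tuple[pd.DataFrame, float]:
    """ROC curve over all distinct-probability thresholds and rank AUC.

    The AUC is the Mann-Whitney rank statistic (ties counted half),
    which equals the trapezoidal area under the swept curve.
    """
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(probabilities, dtype=float)
    npos, nneg = int(y.sum()), int((~y).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both label values must be present")

    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep the last index of each tied-probability run (threshold sweep)
    last = np.r_[np.nonzero(np.diff(ps))[0], len(ps) - 1]
    tpr = np.r_[0.0, tps[last] / npos]
    fpr = np.r_[0.0, fps[last] / nneg]
    thresholds = np.r_[np.inf, ps[last]]
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})

    from scipy.stats import rankdata

    ranks = rankdata(p)
    auc = (ranks[y].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    return curve, float(auc)


def horizon_predictions(
    nhpp_fit,
    windows,
    starts: dict[str, float],
    horizon: float,
    exclude_censored: bool = False,
) -> list[HorizonPrediction]:
    """Per-subject horizon predictions with observed labels.

    ``starts`` maps subject_id to the prediction start s on the
    subject's week axis.  The observed label is whether an event falls
    in (s, s+h].  Subjects whose window ends before s+h are by default
    labeled by the events observed up to the window end; with
    ``exclude_censored`` they are dropped instead.
    """
    out = []
    for w in windows:
        s = starts[w.subject_id]
        if exclude_censored and w.R < s + horizon:
            continue
        p = event_probability(nhpp_fit, w.x, s, horizon)
        label = bool(np.any((w.event_times > s) & (w.event_times <= s + horizon)))
        out.append(HorizonPrediction(w.subject_id, s, horizon, p, label))
    return out
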