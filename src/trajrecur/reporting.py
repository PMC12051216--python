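"""Descriptive outputs: baseline tables, coincidence matrices, curve exports."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import Cohort, MED_FLAGS, PRIOR_FLAGS
from .lcgm import LCGMFit, predict_trajectory


def coincidence_matrix(
    labels_a: dict[str, object], labels_b: dict[str, object]
) -> pd.DataFrame:
    """Row-normalized coincidence rates between two labelings.

    Entry (a, b) is the share of subjects labeled ``a`` in the first
    labeling that are labeled ``b`` in the second, over the subjects
    present in both; subjects in only one labeling are dropped with a
    warning.  Rows sum to 1.
    """
    shared = sorted(set(labels_a) & set(labels_b))
    if not shared:
        raise ValueError("the two labelings share no subjects")
    dropped = len(set(labels_a) | set(labels_b)) - len(shared)
    if dropped:
        warnings.warn(
            f"{dropped} subject(s) present in only one labeling were dropped",
            stacklevel=2,
        )
    a = pd.Series({s: labels_a[s] for s in shared})
    b = pd.Series({s: labels_b[s] for s in shared})
    counts = pd.crosstab(a, b)
    return counts.div(counts.sum(axis=1), axis=0)


def baseline_table(cohort: Cohort, labels: dict[str, int]) -> pd.DataFrame:
    """Per-class baseline summary (one row per class).

    Columns mirror a registry baseline table: class size and share,
    mean +- SD age and baseline HbA1c, % male, ethnicity %, prior-flag
    and medication %, mean measurement count and observation period.
    """
    missing = [s for s in cohort.subjects if s not in labels]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} subject(s)")
    n_total = cohort.n_subjects
    rows = []
    for cls in sorted(set(labels.values())):
        ids = [s for s in cohort.subjects if labels[s] == cls]
        row: dict = {"class": cls, "n": len(ids)}
        if not ids:
            rows.append(row)
            continue
        subs = [cohort.subjects[s] for s in ids]
        sers = [cohort.series[s] for s in ids if s in cohort.series]
        ages = np.array([s.age_at_ddd for s in subs])
        base = np.array(
            [s.baseline_hba1c for s in subs if s.baseline_hba1c is not None]
        )
        row.update({
            "pct": 100.0 * len(ids) / n_total,
            "age_mean": ages.mean(), "age_sd": ages.std(ddof=1) if len(ages) > 1 else 0.0,
            "male_pct": 100.0 * np.mean([s.sex == "male" for s in subs]),
            "baseline_hba1c_mean": base.mean() if len(base) else np.nan,
            "baseline_hba1c_sd": base.std(ddof=1) if len(base) > 1 else 0.0,
        })
        for eth in ("Chinese", "Malay", "Indian", "Other"):
            row[f"eth_{eth}_pct"] = 100.0 * np.mean([s.ethnicity == eth for s in subs])
        for f in PRIOR_FLAGS:
            row[f"prior_{f}_pct"] = 100.0 * np.mean(
                [s.prior_flags.get(f, False) for s in subs]
            )
        for f in MED_FLAGS:
            row[f"med_{f}_pct"] = 100.0 * np.mean(
                [s.medication_flags.get(f, False) for s in subs]
            )
        if sers:
            row["mean_n_measurements"] = np.mean([len(s.times) for s in sers])
            row["mean_obs_period_weeks"] = np.mean([s.times[-1] for s in sers])
        rows.append(row)
    return pd.DataFrame(rows)


def export_curves(fit_or_curves, grid, out_path=None) -> pd.DataFrame:
    """Long-format (class, t_weeks, value) export of per-class curves.

    Accepts a fitted LCGM (mean trajectories on ``grid``) or a mapping
    of class label to an array of values already evaluated on ``grid``.
    """
    grid = np.asarray(grid, dtype=float)
    rows = []
    if isinstance(fit_or_curves, LCGMFit):
        curves = {
            k: predict_trajectory(fit_or_curves, k, grid)
            for k in range(1, fit_or_curves.K + 1)
        }
    else:
        curves = dict(fit_or_curves)
    for cls, values in curves.items():
        values = np.asarray(values, dtype=float)
        if len(values) != len(grid):
            raise ValueError(f"class {cls}: curve length != grid length")
        for t, v in zip(grid, values):
            rows.append({"class": cls, "t_weeks": t, "value": v})
    df = pd.DataFrame(rows, columns=["class", "t_weeks", "value"])
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
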