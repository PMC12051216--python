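"""Joint selection of knot count, knot strategy and number of classes.

The iterative procedure alternates two BIC-driven searches: with the
class count fixed, scan interior-knot counts for both placement
strategies and keep the pair with the smallest BIC; with the knots
fixed, scan class counts with a cross-validated BIC and keep the
smallest; repeat until the (knots, strategy, K) triple is stable.
Ties always go to the smaller model (parsimony), and to equidistant
placement between strategies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .lcgm import bic, fit_lcgm, marginal_loglik
from .splines import KNOT_CANDIDATES, BasisSpec, make_spec

STRATEGIES = ("equidistant", "equipotent")


class SelectionError(RuntimeError):
    pass


@dataclass
class SelectionResult:
    chosen_K: int
    chosen_n_interior: int
    chosen_strategy: str
    trace: list[dict] = field(default_factory=list)
    stable: bool = False


def _pooled_times(cohort: Cohort) -> np.ndarray:
    return np.concatenate([s.times for s in cohort.series.values()])


def _subcohort(cohort: Cohort, ids) -> Cohort:
    ids = set(ids)
    return Cohort(
        subjects={k: v for k, v in cohort.subjects.items() if k in ids},
        series={k: v for k, v in cohort.series.items() if k in ids},
        windows={k: v for k, v in cohort.windows.items() if k in ids},
    )


def select_knots(
    cohort: Cohort,
    K: int,
    candidates=KNOT_CANDIDATES,
    strategies=STRATEGIES,
    n_starts: int = 10,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[int, str, pd.DataFrame]:
    """BIC scan over (interior-knot count, strategy) pairs at fixed K.

    Returns the argmin pair and the full BIC table; ties break to the
    smaller knot count, then equidistant.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    times = _pooled_times(cohort)
    n = cohort.n_subjects
    rows = []
    for n_int in candidates:
        for strat in strategies:
            try:
                spec = make_spec(times, n_int, strat)
                fit = fit_lcgm(cohort, K, spec, n_starts=n_starts,
                               max_iter=max_iter, seed=seed)
                rows.append({"n_interior": n_int, "strategy": strat,
                             "bic": bic(fit, n), "loglik": fit.loglik})
            except Exception as exc:  # degenerate knots or fit
                warnings.warn(f"knot candidate ({n_int}, {strat}) failed: {exc}",
                              stacklevel=2)
                rows.append({"n_interior": n_int, "strategy": strat,
                             "bic": np.inf, "loglik": np.nan})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["bic"])]
    if finite.empty:
        raise SelectionError("all knot-candidate fits failed")
    ordered = finite.sort_values(
        ["bic", "n_interior", "strategy"]  # equidistant < equipotent alphabetically
    )
    best = ordered.iloc[0]
    return int(best["n_interior"]), str(best["strategy"]), table


def cv_bic(
    cohort: Cohort,
    K: int,
    spec: BasisSpec,
    n_folds: int = 10,
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 200,
) -> float:
    """Mean held-out BIC over a subject-level K-fold split.

    Each fold's model is fitted on the remaining folds; the held-out
    BIC is -2 * (held-out marginal loglik) + n_params * log(n_heldout).
    Rankings across K are driven by the held-out likelihood term.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids = np.array(cohort.subject_ids())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, n_folds)
    scores = []
    for f, idx in enumerate(folds):
        held = set(ids[idx])
        if len(held) < K:
            raise SelectionError(f"fold {f} has fewer subjects than classes")
        train = _subcohort(cohort, set(ids) - held)
        test = _subcohort(cohort, held)
        fit = fit_lcgm(train, K, spec, n_starts=n_starts, max_iter=max_iter,
                       seed=seed + f)
        ll = marginal_loglik(fit, test)
        scores.append(-2.0 * ll + fit.n_params * np.log(test.n_subjects))
    return float(np.mean(scores))


def select_num_classes(
    cohort: Cohort,
    spec: BasisSpec,
    K_range=range(1, 11),
    n_folds: int = 10,
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 200,
    method: str = "cv",
) -> tuple[int, pd.DataFrame]:
    """Class-count selection by cross-validated (or single-fit) BIC.

    ``method='cv'`` scores each K with :func:`cv_bic`; ``method='bic'``
    uses the ordinary BIC of one full-data fit (cheaper, same argmin on
    well-separated data).  Ties break to the smaller K; Ks whose fits
    fail are excluded with a warning.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    rows = []
    for K in K_range:
        try:
            if method == "cv":
                score = cv_bic(cohort, K, spec, n_folds=n_folds, seed=seed,
                               n_starts=n_starts, max_iter=max_iter)
            elif method == "bic":
                fit = fit_lcgm(cohort, K, spec, n_starts=n_starts,
                               max_iter=max_iter, seed=seed)
                score = bic(fit, cohort.n_subjects)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({"K": K, "bic": score})
        except (SelectionError, RuntimeError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"K={K} fit failed and was excluded: {exc}", stacklevel=2)
            rows.append({"K": K, "bic": np.inf})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["bic"])]
    if finite.empty:
        raise SelectionError("every class count failed to fit")
    best = finite.sort_values(["bic", "K"]).iloc[0]
    return int(best["K"]), table


def iterate_selection(
    cohort: Cohort,
    K0: int = 3,
    candidates=KNOT_CANDIDATES,
    strategies=STRATEGIES,
    K_range=range(1, 11),
    n_folds: int = 10,
    seed: int = 0,
    max_rounds: int = 5,
    n_starts: int = 10,
    max_iter: int = 200,
    method: str = "cv",
) -> SelectionResult:
    """Alternate knot selection and class-count selection to a fixed point.

    Starting from K0 classes, each round picks the best (knots,
    strategy) at the current K, then the best K at the chosen knots;
    the procedure stops when the triple repeats or after
    ``max_rounds`` rounds (``stable`` records which).
    """
    if K0 not in list(K_range):
        raise ValueError("K0 must be inside K_range")
    times = _pooled_times(cohort)
    K = K0
    trace: list[dict] = []
    prev_triple = None
    stable = False
    for rnd in range(1, max_rounds + 1):
        n_int, strat, knot_table = select_knots(
            cohort, K, candidates, strategies, n_starts=n_starts,
            max_iter=max_iter, seed=seed,
        )
        spec = make_spec(times, n_int, strat)
        K, class_table = select_num_classes(
            cohort, spec, K_range, n_folds=n_folds, seed=seed,
            n_starts=n_starts, max_iter=max_iter, method=method,
        )
        triple = (K, n_int, strat)
        trace.append({
            "round": rnd, "K": K, "n_interior": n_int, "strategy": strat,
            "knot_bic": knot_table.to_dict("records"),
            "class_bic": class_table.to_dict("records"),
        })
        if triple == prev_triple:
            stable = True
            break
        prev_triple = triple
    return SelectionResult(
        chosen_K=K, chosen_n_interior=n_int, chosen_strategy=strat,
        trace=trace, stable=stable,
    )
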