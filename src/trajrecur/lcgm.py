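"""Latent class growth model: mixture of B-spline trajectories with
class-specific random intercepts and shared residual noise, fitted by EM.

Subject i in class k has

    y_i ~ N( B_i beta_k,  sigma_b_k^2 J + sigma_e^2 I )

where B_i is the subject's B-spline design matrix and J the all-ones
matrix.  The rank-1 covariance structure makes every per-subject
quantity computable in O(n_i): with c = sigma_b^2/(sigma_e^2 + n sigma_b^2),

    Sigma^-1 = (I - c 11') / sigma_e^2
    log det  = (n-1) log sigma_e^2 + log(sigma_e^2 + n sigma_b^2).

The E-step augments both the class label and the random intercept, so
the M-step has closed forms: tau-weighted GLS for beta_k and moment
updates for the variance components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .cohort import Cohort, MeasurementSeries
from .splines import BasisSpec, basis_matrix

_LOG2PI = np.log(2 * np.pi)
_SIGMA_E_FLOOR = 1e-4


class DegenerateFitError(RuntimeError):
    """Every EM start collapsed to an empty class."""


class _EmptyClass(Exception):
    pass


@dataclass
class LCGMFit:
    """Fitted latent class growth model, classes in descending-pi order."""

    K: int
    spec: BasisSpec
    beta: np.ndarray          # (K, m) spline coefficients, HbA1c %
    sigma_b: np.ndarray       # (K,) random-intercept SDs
    sigma_e: float            # shared residual SD
    pi: np.ndarray            # (K,) mixing proportions
    loglik: float
    n_params: int
    converged: bool
    n_iter: int

    def to_json(self, path=None) -> str:
        d = {
            "K": self.K,
            "spec": self.spec.to_dict(),
            "beta": self.beta.tolist(),
            "sigma_b": self.sigma_b.tolist(),
            "sigma_e": self.sigma_e,
            "pi": self.pi.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "LCGMFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            K=int(d["K"]),
            spec=BasisSpec.from_dict(d["spec"]),
            beta=np.asarray(d["beta"], dtype=float),
            sigma_b=np.asarray(d["sigma_b"], dtype=float),
            sigma_e=float(d["sigma_e"]),
            pi=np.asarray(d["pi"], dtype=float),
            loglik=float(d["loglik"]),
            n_params=int(d["n_params"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
        )


def n_params_lcgm(K: int, m: int) -> int:
    """K*m spline coefficients + K intercept SDs + 1 residual SD + (K-1) pi."""
    return K * m + K + 1 + (K - 1)


# ---------------------------------------------------------------------------
# Sufficient statistics


class _Suff:
    """Per-subject statistics that make EM iterations O(N m^2)."""

    def __init__(self, cohort: Cohort, spec: BasisSpec):
        self.ids = cohort.subject_ids()
        N = len(self.ids)
        m = spec.m
        self.n = np.zeros(N)
        self.yty = np.zeros(N)
        self.ysum = np.zeros(N)
        self.U = np.zeros((N, m))       # B' 1
        self.S = np.zeros((N, m))       # B' y
        self.G = np.zeros((N, m, m))    # B' B
        for i, sid in enumerate(self.ids):
            ser = cohort.series[sid]
            B = basis_matrix(ser.times, spec)
            y = ser.values
            self.n[i] = len(y)
            self.yty[i] = y @ y
            self.ysum[i] = y.sum()
            self.U[i] = B.sum(axis=0)
            self.S[i] = B.T @ y
            self.G[i] = B.T @ B
        self.N = N
        self.m = m


def _class_stats(suff: _Suff, beta_k, sigma_b_k, sigma_e):
    """Per-subject (loglik, residual sum o=1'r, residual SS q=r'r, c)."""
    q = suff.yty - 2 * (suff.S @ beta_k) + np.einsum(
        "nij,i,j->n", suff.G, beta_k, beta_k
    )
    o = suff.ysum - suff.U @ beta_k
    se2 = sigma_e ** 2
    sb2 = sigma_b_k ** 2
    c = sb2 / (se2 + suff.n * sb2)
    ll = -0.5 * (
        suff.n * (_LOG2PI + np.log(se2))
        + np.log1p(suff.n * sb2 / se2)
        + (q - c * o ** 2) / se2
    )
    return ll, o, q, c


def class_marginal_loglik(
    series: MeasurementSeries,
    beta_k,
    sigma_b_k: float,
    sigma_e: float,
    spec: BasisSpec,
) -> float:
    """Marginal log density of one series under a single class.

    Multivariate normal with mean B beta_k and compound-symmetric
    covariance sigma_b_k^2 J + sigma_e^2 I, evaluated in O(n) via the
    rank-1 Woodbury identity.
    """
    if sigma_e <= 0:
        raise ValueError("sigma_e must be > 0")
    if len(series.times) == 0:
        raise ValueError("series must be non-empty")
    beta_k = np.asarray(beta_k, dtype=float)
    B = basis_matrix(series.times, spec)
    r = series.values - B @ beta_k
    n = len(r)
    se2 = sigma_e ** 2
    sb2 = sigma_b_k ** 2
    c = sb2 / (se2 + n * sb2)
    o = r.sum()
    return float(
        -0.5 * (
            n * (_LOG2PI + np.log(se2))
            + np.log1p(n * sb2 / se2)
            + (r @ r - c * o ** 2) / se2
        )
    )


# ---------------------------------------------------------------------------
# EM


def _loglik_matrix_from_params(suff, beta, sigma_b, sigma_e):
    K = beta.shape[0]
    L = np.empty((suff.N, K))
    for k in range(K):
        L[:, k], _, _, _ = _class_stats(suff, beta[k], sigma_b[k], sigma_e)
    return L


def _em_from_tau(suff: _Suff, tau, max_iter, tol, sigma_e0=0.5, sigma_b0=0.3):
    """Run EM from initial responsibilities; returns raw (unordered) params."""
    N, m = suff.N, suff.m
    K = tau.shape[1]
    sigma_e = sigma_e0
    sigma_b = np.full(K, sigma_b0)
    beta = np.zeros((K, m))
    loglik = -np.inf
    trace = []
    total_obs = suff.n.sum()

    for it in range(1, max_iter + 1):
        wsum = tau.sum(axis=0)
        if np.any(wsum < 1e-12 * N):
            raise _EmptyClass
        pi = wsum / N

        # M-step: tau-weighted GLS for beta_k, then variance updates
        se2 = sigma_e ** 2
        sse = 0.0
        for k in range(K):
            sb2 = sigma_b[k] ** 2
            c = sb2 / (se2 + suff.n * sb2)
            w = tau[:, k]
            A = np.einsum("n,nij->ij", w, suff.G) - np.einsum(
                "n,ni,nj->ij", w * c, suff.U, suff.U
            )
            b = np.einsum("n,ni->i", w, suff.S) - (w * c * suff.ysum) @ suff.U
            A.flat[:: m + 1] += 1e-9 * max(1.0, A.flat[:: m + 1].max())
            beta[k] = np.linalg.solve(A, b)

            # random-intercept posterior given the new mean
            _, o, q, c = _class_stats(suff, beta[k], sigma_b[k], sigma_e)
            mu_b = c * o
            v_b = se2 * c
            sigma_b[k] = np.sqrt(max((w @ (mu_b ** 2 + v_b)) / wsum[k], 0.0))
            sse += w @ (q - 2 * mu_b * o + suff.n * (mu_b ** 2 + v_b))
        sigma_e = max(np.sqrt(sse / total_obs), _SIGMA_E_FLOOR)

        # E-step
        L = _loglik_matrix_from_params(suff, beta, sigma_b, sigma_e)
        logw = L + np.log(pi)
        per_subject = logsumexp(logw, axis=1)
        new_loglik = float(per_subject.sum())
        tau = np.exp(logw - per_subject[:, None])
        trace.append(new_loglik)

        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            return beta, sigma_b, sigma_e, pi, new_loglik, True, it, trace
        loglik = new_loglik

    return beta, sigma_b, sigma_e, pi, loglik, False, max_iter, trace


def _subject_features(suff: _Suff, spec: BasisSpec, n_points: int = 5):
    """Longitudinal k-means features: per-subject curves at a fixed grid.

    Each subject's observations are ridge-projected onto the model
    basis with shrinkage toward the pooled mean curve (subjects with
    few observations fall back to it), then evaluated at ``n_points``
    interior grid times.  Clustering these profiles separates classes
    by both level and shape.
    """
    m = suff.m
    lam = 1.0
    G_tot = suff.G.sum(axis=0)
    G_tot_reg = G_tot + lam * np.eye(m)
    c0 = np.linalg.solve(G_tot_reg, suff.S.sum(axis=0))
    knots = np.asarray(spec.interior_knots)
    if len(knots) >= n_points:
        # interior knots track the data density (quantiles for equipotent)
        grid = knots[np.linspace(0, len(knots) - 1, n_points).round().astype(int)]
    else:
        lo, hi = spec.boundary
        grid = lo + (hi - lo) * (np.arange(1, n_points + 1) / (n_points + 1))
    grid = np.concatenate([[spec.boundary[0]], grid])   # include baseline level
    Bg = basis_matrix(grid, spec)
    feats = np.empty((suff.N, len(grid)))
    for i in range(suff.N):
        coef = np.linalg.solve(
            suff.G[i] + lam * np.eye(m), suff.S[i] + lam * c0
        )
        feats[i] = Bg @ coef
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    return (feats - feats.mean(axis=0)) / scale


def fit_lcgm(
    cohort: Cohort,
    K: int,
    spec: BasisSpec,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float | None = None,
    seed: int = 0,
) -> LCGMFit:
    """Fit the K-class spline LCGM by EM, best of ``n_starts`` starts.

    Responsibilities are initialized by k-means on per-subject
    shrinkage-projected curve profiles (longitudinal k-means); the
    first start uses the best of ten k-means seedings, the remaining
    starts single random seedings.  Classes in the returned fit are
    sorted by descending pi (ties by the first spline coefficient).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    suff = _Suff(cohort, spec)
    N = suff.N
    if N == 0:
        raise ValueError("empty cohort")
    if tol is None:
        tol = 1e-6 * N
    rng = np.random.default_rng(seed)

    def _tau_from_labels(labels):
        tau = np.full((N, K), 1e-3)
        tau[np.arange(N), labels] = 1.0
        return tau / tau.sum(axis=1, keepdims=True)

    inits = []
    if K == 1:
        inits.append(np.ones((N, 1)))
        n_starts = 1
    else:
        X = _subject_features(suff, spec)
        km = KMeans(n_clusters=K, n_init=10, random_state=int(rng.integers(2**31)))
        inits.append(_tau_from_labels(km.fit_predict(X)))
        for _ in range(n_starts - 1):
            # restarts: single-init k-means from a random seeding
            km = KMeans(
                n_clusters=K, n_init=1, init="random",
                random_state=int(rng.integers(2**31)),
            )
            inits.append(_tau_from_labels(km.fit_predict(X)))

    best = None
    for tau0 in inits:
        try:
            result = _em_from_tau(suff, tau0, max_iter, tol)
        except _EmptyClass:
            # retry once from a fresh random initialization
            labels = rng.integers(K, size=N)
            tau = np.full((N, K), 1e-3)
            tau[np.arange(N), labels] = 1.0
            try:
                result = _em_from_tau(
                    suff, tau / tau.sum(axis=1, keepdims=True), max_iter, tol
                )
            except _EmptyClass:
                continue
        if best is None or result[4] > best[4]:
            best = result
    if best is None:
        raise DegenerateFitError("all EM starts produced an empty class")

    beta, sigma_b, sigma_e, pi, loglik, converged, n_iter, _ = best
    order = np.lexsort((beta[:, 0], -pi))
    return LCGMFit(
        K=K,
        spec=spec,
        beta=beta[order],
        sigma_b=sigma_b[order],
        sigma_e=float(sigma_e),
        pi=pi[order],
        loglik=loglik,
        n_params=n_params_lcgm(K, spec.m),
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Posteriors, assignment, BIC, trajectories


def loglik_matrix(fit: LCGMFit, cohort: Cohort) -> tuple[list[str], np.ndarray]:
    """Subject ids and the (N, K) matrix of per-class marginal logliks."""
    suff = _Suff(cohort, fit.spec)
    return suff.ids, _loglik_matrix_from_params(
        suff, fit.beta, fit.sigma_b, fit.sigma_e
    )


def marginal_loglik(fit: LCGMFit, cohort: Cohort) -> float:
    """Total mixture marginal log-likelihood of a (possibly new) cohort."""
    _, L = loglik_matrix(fit, cohort)
    return float(logsumexp(L + np.log(fit.pi), axis=1).sum())


def posterior_probs(fit: LCGMFit, cohort: Cohort):
    """Posterior class-membership matrix (rows sum to 1)."""
    import pandas as pd

    ids, L = loglik_matrix(fit, cohort)
    logw = L + np.log(fit.pi)
    tau = np.exp(logw - logsumexp(logw, axis=1)[:, None])
    return pd.DataFrame(tau, index=ids, columns=np.arange(1, fit.K + 1))


def assign_class(fit: LCGMFit, series: MeasurementSeries) -> int:
    """Most probable class (1-based) for an unseen subject's series.

    Ties go to the lower class index.
    """
    ll = np.array(
        [
            class_marginal_loglik(series, fit.beta[k], fit.sigma_b[k], fit.sigma_e, fit.spec)
            for k in range(fit.K)
        ]
    )
    score = ll + np.log(fit.pi)
    best = score.max()
    # numerically exact ties go to the lower class index
    return int(np.nonzero(score >= best - 1e-9 * (1 + abs(best)))[0][0]) + 1


def bic(fit: LCGMFit, n_subjects: int) -> float:
    """Bayesian information criterion: -2 loglik + n_params log(n_subjects)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * fit.loglik + fit.n_params * np.log(n_subjects)


def predict_trajectory(fit: LCGMFit, class_index: int, times) -> np.ndarray:
    """Class mean HbA1c trajectory B(times) beta_k (class_index 1-based)."""
    if not 1 <= class_index <= fit.K:
        raise ValueError(f"class_index must be in 1..{fit.K}")
    return basis_matrix(np.asarray(times, dtype=float), fit.spec) @ fit.beta[class_index - 1]
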