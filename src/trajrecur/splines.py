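"""Cubic B-spline bases with equidistant or equipotent interior knots.

Equidistant knots subdivide the boundary interval into equal widths;
equipotent knots sit at empirical quantiles of the pooled observation
times so every inter-knot interval holds the same number of data
points.  Boundary knots are clamped (repeated degree+1 times) and
evaluation times outside the boundary are clamped to it, since
unpenalized B-splines extrapolate unstably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

#: candidate interior-knot counts scanned during model selection
KNOT_CANDIDATES = (5, 10, 15, 20, 25, 30, 35, 40)


class DegenerateKnotsError(ValueError):
    """Quantile knots coincide beyond repair for the requested count."""


@dataclass(frozen=True)
class BasisSpec:
    """A fully determined B-spline basis on a boundary interval."""

    degree: int
    n_interior: int
    strategy: str
    boundary: tuple[float, float]
    interior_knots: tuple[float, ...] = field(default=())

    @property
    def m(self) -> int:
        """Basis dimension: n_interior + degree + 1."""
        return len(self.interior_knots) + self.degree + 1

    def full_knots(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.full(self.degree + 1, lo),
                np.asarray(self.interior_knots, dtype=float),
                np.full(self.degree + 1, hi),
            ]
        )

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "n_interior": self.n_interior,
            "strategy": self.strategy,
            "boundary": list(self.boundary),
            "interior_knots": list(self.interior_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            degree=int(d["degree"]),
            n_interior=int(d["n_interior"]),
            strategy=str(d["strategy"]),
            boundary=tuple(d["boundary"]),
            interior_knots=tuple(d["interior_knots"]),
        )


def place_knots(
    times,
    n_interior: int,
    strategy: str = "equipotent",
    boundary: tuple[float, float] | None = None,
) -> np.ndarray:
    """Interior knot vector for one of the two placement strategies.

    ``equidistant`` subdivides the boundary interval equally;
    ``equipotent`` places knots at the j/(n_interior+1) empirical
    quantiles of the pooled times, j = 1..n_interior.  Tied quantiles
    are collapsed to unique values with a warning; if no interior knot
    survives, a :class:`DegenerateKnotsError` is raised.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if n_interior < 1:
        raise ValueError("n_interior must be >= 1")
    if boundary is None:
        boundary = (float(times.min()), float(times.max()))
    lo, hi = boundary
    if not hi > lo:
        raise ValueError(f"degenerate boundary {boundary}")

    if strategy == "equidistant":
        return np.linspace(lo, hi, n_interior + 2)[1:-1]
    if strategy != "equipotent":
        raise ValueError(f"unknown strategy {strategy!r}")

    q = np.arange(1, n_interior + 1) / (n_interior + 1)
    knots = np.quantile(times, q)
    knots = knots[(knots > lo) & (knots < hi)]
    knots = np.unique(knots)
    if knots.size == 0:
        raise DegenerateKnotsError(
            f"all {n_interior} quantile knots coincide with the boundary or each other"
        )
    if knots.size < n_interior:
        warnings.warn(
            f"equipotent placement collapsed {n_interior} knots to {knots.size} "
            "unique interior values",
            stacklevel=2,
        )
    return knots


def make_spec(
    times,
    n_interior: int,
    strategy: str = "equipotent",
    degree: int = 3,
    boundary: tuple[float, float] | None = None,
) -> BasisSpec:
    """Convenience constructor: place knots and freeze them into a spec."""
    times = np.asarray(times, dtype=float)
    if boundary is None:
        boundary = (0.0, float(times.max()))
    knots = place_knots(times, n_interior, strategy, boundary)
    return BasisSpec(
        degree=degree,
        n_interior=n_interior,
        strategy=strategy,
        boundary=(float(boundary[0]), float(boundary[1])),
        interior_knots=tuple(float(k) for k in knots),
    )


def basis_matrix(times, spec: BasisSpec) -> np.ndarray:
    """Dense design matrix of B-spline basis evaluations.

    Rows are a partition of unity (sum to 1, entries >= 0).  Times
    outside the boundary are clamped to it.  An empty ``times`` yields
    an empty (0, m) matrix.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros((0, spec.m))
    clamped = np.clip(times, spec.boundary[0], spec.boundary[1])
    return BSpline.design_matrix(clamped, spec.full_knots(), spec.degree).toarray()
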