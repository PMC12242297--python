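"""Penalized B-spline (P-spline) basis for smooth time trends.

Cubic B-splines on evenly spaced knots over the observed time span, with
a difference penalty on the coefficients. The penalty matrix is D'D for
the requested difference order, so its null space contains exactly the
polynomial coefficient sequences of degree below the order (order 2
leaves straight-line coefficient vectors unpenalized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_spline_basis"]

_DEGREE = 3  # cubic


@dataclass
class SplineBasis:
    """A clamped cubic B-spline basis of ``k`` functions on [lo, hi]."""

    knots: np.ndarray
    k: int
    penalty_order: int

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[_DEGREE]), float(self.knots[-_DEGREE - 1])

    def design(self, times, clip: bool = True) -> np.ndarray:
        """Evaluate the basis at ``times`` (n x k matrix).

        Points outside the domain are clipped to its boundary when
        ``clip`` is set (callers flag extrapolation separately); otherwise
        evaluation outside the domain raises.
        """
        t = np.asarray(times, dtype=float)
        lo, hi = self.domain
        if clip:
            t = np.clip(t, lo, hi)
        elif (t < lo).any() or (t > hi).any():
            raise ValueError("times outside the basis domain")
        B = BSpline.design_matrix(t, self.knots, _DEGREE).toarray()
        return B

    @property
    def penalty(self) -> np.ndarray:
        """k x k difference-penalty matrix D'D (positive semidefinite)."""
        D = np.diff(np.eye(self.k), n=self.penalty_order, axis=0)
        return D.T @ D


def build_spline_basis(
    times, k: int = 10, penalty_order: int = 2
) -> tuple[np.ndarray, np.ndarray, SplineBasis]:
    """Build a P-spline basis over the span of the observed times.

    Returns ``(B, S, basis)``: the n x k design matrix (rows sum to 1 by
    the B-spline partition of unity), the k x k difference-penalty matrix,
    and the reusable basis object for evaluating new time points.

    ``k`` counts basis functions; it must be at least ``penalty_order + 2``
    and at least 4 (the cubic degree + 1). The observed times must span a
    positive interval.
    """
    t = np.asarray(times, dtype=float)
    if k < max(penalty_order + 2, _DEGREE + 1):
        raise ValueError(
            f"k={k} too small: need k >= max(penalty order + 2, 4)"
        )
    lo, hi = float(t.min()), float(t.max())
    if not hi > lo:
        raise ValueError("degenerate time span: times must span a positive interval")
    n_interior = k - _DEGREE - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(_DEGREE + 1, lo), interior, np.full(_DEGREE + 1, hi)]
    )
    basis = SplineBasis(knots=knots, k=k, penalty_order=penalty_order)
    return basis.design(t), basis.penalty, basis
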