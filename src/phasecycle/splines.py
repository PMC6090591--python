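"""B-spline design matrices evaluated by the Cox-de Boor recursion.

Two bases are used in the pipeline: a minimal cubic basis with df = 3 and no
interior knots for the differential-expression design (the intercept column is
excluded, so the basis vanishes at the left boundary), and a rich cubic basis
with equally spaced interior knots for the penalized-spline cluster means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _deboor_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """All B-spline basis functions of ``degree`` on ``knots`` at points ``x``.

    The right boundary is treated as closed: basis functions are evaluated by
    the standard recursion on half-open intervals, and points equal to the
    last knot are assigned to the final non-empty interval.
    """
    x = np.asarray(x, dtype=float)
    n_basis = len(knots) - degree - 1
    if n_basis < 1:
        raise ValueError("too few knots for requested degree")
    # degree-0: indicator of [t_i, t_{i+1}), closed at the global right end
    B = np.zeros((len(x), len(knots) - 1))
    right = knots[-1]
    for i in range(len(knots) - 1):
        lo, hi = knots[i], knots[i + 1]
        if lo == hi:
            continue
        inside = (x >= lo) & ((x < hi) | ((hi == right) & (x == right)))
        B[inside, i] = 1.0
    for d in range(1, degree + 1):
        nxt = np.zeros((len(x), B.shape[1] - 1))
        for i in range(B.shape[1] - 1):
            denom1 = knots[i + d] - knots[i]
            denom2 = knots[i + d + 1] - knots[i + 1]
            term = np.zeros(len(x))
            if denom1 > 0:
                term = term + (x - knots[i]) / denom1 * B[:, i]
            if denom2 > 0:
                term = term + (knots[i + d + 1] - x) / denom2 * B[:, i + 1]
            nxt[:, i] = term
        B = nxt
    return B[:, :n_basis]


@dataclass
class SplineBasis:
    """df = 3 cubic time basis for the DE designs (intercept excluded)."""

    times: np.ndarray
    basis: np.ndarray  # (n_samples, 3)
    boundary: tuple[float, float] = (0.0, 96.0)

    @property
    def df(self) -> int:
        return self.basis.shape[1]


def build_spline_basis(times, boundary: tuple[float, float] = (0.0, 96.0)) -> SplineBasis:
    """Cubic B-spline basis, df = 3, no interior knots, intercept excluded.

    With boundary knots (0, 96) and no interior knots the basis reduces to the
    three non-constant cubic Bernstein polynomials of t/96, so the row at
    t = 0 is (0, 0, 0) and the row at t = 96 is (0, 0, 1).
    """
    times = np.asarray(times, dtype=float)
    lo, hi = boundary
    if times.min() < lo or times.max() > hi:
        raise ValueError(
            f"times outside boundary knots [{lo}, {hi}]: "
            f"range ({times.min()}, {times.max()})"
        )
    knots = np.array([lo] * 4 + [hi] * 4, dtype=float)
    full = _deboor_design(times, knots, degree=3)  # 4 columns, partition of unity
    return SplineBasis(times, full[:, 1:], (lo, hi))


def pspline_basis(times, n_interior: int = 5,
                  boundary: tuple[float, float] = (0.0, 96.0)) -> np.ndarray:
    """Rich cubic basis (intercept kept) with equally spaced interior knots."""
    times = np.asarray(times, dtype=float)
    lo, hi = boundary
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    return _deboor_design(times, knots, degree=3)


def second_difference_penalty(n_basis: int) -> np.ndarray:
    """P-spline penalty matrix D2' D2 on adjacent coefficient differences."""
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    return D.T @ D
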