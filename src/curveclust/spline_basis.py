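"""Natural cubic spline basis: construction, analytic derivatives, exact Gram matrices.

The p-dimensional natural cubic spline space on a window [a, b] with knots
a = k_1 < k_2 < ... < k_p = b is spanned by the cardinal interpolation basis:
basis function l is the natural cubic spline interpolating the l-th unit
vector at the knots.  A convenient consequence is that the coefficient vector
of any spline in this basis equals its values at the knots; in particular the
affine functions (always contained in the natural spline space) have
coefficients equal to their knot values.

Beyond the boundary knots a natural spline continues linearly (zero second
derivative), which is the extrapolation rule used by :meth:`SplineBasis.design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline, PPoly

from .errors import InfeasibleBasisError

__all__ = ["SplineBasis", "build_basis", "evaluate", "gram", "knot_report_table"]


@dataclass(frozen=True)
class SplineBasis:
    """A p-dimensional natural cubic spline basis on a fixed window.

    Parameters
    ----------
    p:
        Basis dimension (number of knots, boundary included); ``p >= 2``.
    interior_knots:
        Strictly increasing knots strictly inside ``boundary``; there are
        exactly ``p - 2`` of them.
    boundary:
        The window ``(a, b)``; boundary knots sit at the window edges.
    """

    p: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]
    basis_kind: str = "natural-cubic"
    _ppolys: tuple[PPoly, PPoly, PPoly] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        a, b = map(float, self.boundary)
        interior = np.asarray(self.interior_knots, dtype=float).reshape(-1)
        if not a < b:
            raise ValueError(f"degenerate window [{a}, {b}]")
        if self.p < 2:
            raise ValueError("basis dimension p must be >= 2")
        if len(interior) != self.p - 2:
            raise ValueError(
                f"natural cubic basis of dimension {self.p} needs exactly "
                f"{self.p - 2} interior knots, got {len(interior)}"
            )
        if len(interior) and not (
            np.all(np.diff(interior) > 0) and interior[0] > a and interior[-1] < b
        ):
            raise ValueError("interior knots must be strictly increasing inside (a, b)")
        object.__setattr__(self, "interior_knots", interior)
        object.__setattr__(self, "boundary", (a, b))

        knots = self.knots
        # cardinal basis: column l interpolates the l-th unit vector
        coeffs = np.empty((4, self.p - 1, self.p))
        for l in range(self.p):
            e = np.zeros(self.p)
            e[l] = 1.0
            coeffs[:, :, l] = CubicSpline(knots, e, bc_type="natural").c
        p0 = PPoly(coeffs, knots, extrapolate=False)
        object.__setattr__(self, "_ppolys", (p0, p0.derivative(1), p0.derivative(2)))

    @property
    def knots(self) -> np.ndarray:
        """All knots, boundary included: length p, strictly increasing."""
        a, b = self.boundary
        return np.concatenate(([a], self.interior_knots, [b]))

    def design(self, times, deriv_order: int = 0) -> np.ndarray:
        """Evaluate the q-th derivative of every basis function at ``times``.

        Returns the (len(times), p) design matrix S with S[j, l] = s_l^(q)(t_j),
        computed analytically from the piecewise-cubic representation.  Outside
        the window the natural linear extrapolation is used.
        """
        q = int(deriv_order)
        if q not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {deriv_order}")
        t = np.atleast_1d(np.asarray(times, dtype=float))
        a, b = self.boundary
        out = np.empty((t.size, self.p))
        inside = (t >= a) & (t <= b)
        if inside.any():
            out[inside] = self._ppolys[q](t[inside])
        for mask, edge in ((t < a, a), (t > b, b)):
            if not mask.any():
                continue
            if q == 2:
                out[mask] = 0.0
            elif q == 1:
                out[mask] = self._ppolys[1]([edge])[0]
            else:
                v = self._ppolys[0]([edge])[0]
                d = self._ppolys[1]([edge])[0]
                out[mask] = v + np.outer(t[mask] - edge, d)
        return out

    def gram(self, q: int = 0) -> np.ndarray:
        """Exact Gram matrix M_q with entries integral_a^b s_l^(q) s_m^(q) dt.

        Per-interval Gauss-Legendre quadrature with 4 nodes, exact for the
        degree <= 6 polynomial integrands arising from products of cubics.
        """
        if q not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {q}")
        nodes, weights = leggauss(4)
        knots = self.knots
        M = np.zeros((self.p, self.p))
        for lo, hi in zip(knots[:-1], knots[1:]):
            half = 0.5 * (hi - lo)
            x = lo + half * (nodes + 1.0)
            S = self.design(x, q)  # (4, p)
            M += half * (S.T * weights) @ S
        return 0.5 * (M + M.T)


def build_basis(p: int, grid) -> SplineBasis:
    """Build a natural cubic basis with knots placed from the observed time grid.

    Boundary knots sit at the window edges; the p-2 interior knots are the
    j/(p-1) empirical quantiles (j = 1..p-2) of the pooled *distinct*
    observation times, so that heavily sampled times cannot collapse several
    knots onto one point.

    ``grid`` is a :class:`~curveclust.data_io.TimeGridSummary` or anything
    with ``pooled_times`` / an array of times; the window is taken from the
    grid's ``time_window`` if present, else from the data extremes.
    """
    if p < 2:
        raise InfeasibleBasisError(f"basis dimension p={p} < 2")
    pooled = np.asarray(getattr(grid, "pooled_times", grid), dtype=float).reshape(-1)
    distinct = np.unique(pooled)
    if distinct.size < p:
        raise InfeasibleBasisError(
            f"p={p} exceeds the {distinct.size} distinct observation times"
        )
    window = getattr(grid, "time_window", None)
    a, b = (float(distinct[0]), float(distinct[-1])) if window is None else map(float, window)
    fracs = np.arange(1, p - 1) / (p - 1)
    interior = np.quantile(distinct, fracs) if p > 2 else np.empty(0)
    if len(interior) and (interior[0] <= a or interior[-1] >= b or np.any(np.diff(interior) <= 0)):
        raise InfeasibleBasisError(
            f"quantile knot placement for p={p} produced knots outside ({a}, {b}) "
            "or coincident knots; too few usable distinct times"
        )
    return SplineBasis(p=p, interior_knots=interior, boundary=(a, b))


def evaluate(basis: SplineBasis, times, deriv_order: int = 0) -> np.ndarray:
    """Functional alias for :meth:`SplineBasis.design`."""
    return basis.design(times, deriv_order)


def gram(basis: SplineBasis, q: int = 0) -> np.ndarray:
    """Functional alias for :meth:`SplineBasis.gram`."""
    return basis.gram(q)


def knot_report_table(grid, p_grid) -> "list[dict]":
    """Interior knot positions for each candidate basis dimension.

    Returns one record per (p, knot) pair; infeasible p values are reported
    with a null knot position so the report stays rectangular.
    """
    rows = []
    for p in p_grid:
        try:
            basis = build_basis(p, grid)
        except InfeasibleBasisError:
            rows.append({"p": p, "knot_index": None, "knot_position": None})
            continue
        if basis.interior_knots.size == 0:
            rows.append({"p": p, "knot_index": 0, "knot_position": None})
        for j, pos in enumerate(basis.interior_knots, start=1):
            rows.append({"p": p, "knot_index": j, "knot_position": float(pos)})
    return rows
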