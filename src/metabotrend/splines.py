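"""Natural cubic spline bases anchored at the first harvest week.

A natural cubic spline is piecewise cubic between its knots, has continuous
second derivatives, and is constrained to be linear beyond the boundary
knots (zero second derivative there). With ``df`` degrees of freedom the
basis has ``df`` columns (no intercept); the anchored variant subtracts the
basis row at the earliest time so every column vanishes there, which makes
fitted time effects exact log fold changes from the first week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["SplineBasis", "natural_spline_basis"]


@dataclass
class SplineBasis:
    times: np.ndarray          # evaluation times
    matrix: np.ndarray         # len(times) x df basis values (anchored if requested)
    interior_knots: np.ndarray
    boundary: tuple            # (low, high) boundary knots
    anchored: bool
    anchor_row: np.ndarray     # raw (un-anchored) basis at the anchor time

    @property
    def df(self) -> int:
        return self.matrix.shape[1]

    def evaluate(self, times) -> np.ndarray:
        """Evaluate the (anchored) basis at new times."""
        raw = _natural_basis(np.asarray(times, dtype=float), self.interior_knots, self.boundary)
        if self.anchored:
            raw = raw - self.anchor_row
        return raw


def _natural_basis(x: np.ndarray, interior: np.ndarray, boundary: tuple) -> np.ndarray:
    """Truncated-power construction of the natural cubic spline basis.

    Knots xi_1 < ... < xi_K are boundary + interior knots; with
    d_k(x) = [(x - xi_k)^3_+ - (x - xi_K)^3_+] / (xi_K - xi_k) the columns
    are {x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}}: K-1 functions spanning
    the natural splines without the constant.
    """
    knots = np.sort(np.concatenate([[boundary[0], boundary[1]], interior]))
    K = len(knots)

    def trunc3(v):
        return np.clip(v, 0.0, None) ** 3

    def d(k):
        return (trunc3(x - knots[k]) - trunc3(x - knots[K - 1])) / (knots[K - 1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def natural_spline_basis(times, df: int = 3, boundary=None, anchored: bool = True) -> SplineBasis:
    """Build a natural cubic spline basis on ``times``.

    Interior knots sit at evenly spaced quantiles of the supplied times
    (``df - 1`` of them); boundary knots default to the min/max observed
    time. ``anchored=True`` subtracts the row at the minimum time.
    """
    times = np.asarray(times, dtype=float)
    distinct = np.unique(times)
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    if len(distinct) < df + 1:
        raise ValidationError(
            f"only {len(distinct)} distinct times for a {df}-df natural spline; "
            f"supply at least {df + 1} or lower df in the configuration"
        )
    if boundary is None:
        boundary = (float(distinct.min()), float(distinct.max()))
    # knots from the distinct times: replicate counts must not move knots
    probs = np.arange(1, df) / df
    interior = np.quantile(distinct, probs)
    raw = _natural_basis(times, interior, boundary)
    anchor_time = np.array([float(distinct.min())])
    anchor_row = _natural_basis(anchor_time, interior, boundary)[0]
    matrix = raw - anchor_row if anchored else raw
    return SplineBasis(
        times=times,
        matrix=matrix,
        interior_knots=interior,
        boundary=boundary,
        anchored=anchored,
        anchor_row=anchor_row,
    )
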