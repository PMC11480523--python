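"""Locally weighted polynomial regression (loess).

Classic loess with a tricube kernel: at each query point a polynomial of
the requested degree is fitted by weighted least squares over the
``span``-fraction nearest data points, and the local fit is evaluated at
the query point. No robustness iterations are performed. This matches the
default gaussian-family behaviour of the smoother commonly used to
interpolate wildlife survey series.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LoessCurve", "loess_fit"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


class LoessCurve:
    """A fitted loess smoother, evaluable at any point within the data range.

    Parameters
    ----------
    x, y : array-like
        Training points. ``x`` need not be sorted.
    span : float
        Fraction of the data used in each local fit (0 < span <= 1).
    degree : int
        Degree of the local polynomial (0, 1 or 2 are customary).
    """

    def __init__(self, x, y, span: float = 0.75, degree: int = 2):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (0.0 < span <= 1.0):
            raise ValueError(f"span must be in (0, 1], got {span}")
        if degree < 0:
            raise ValueError("degree must be non-negative")
        n = x.size
        if n < degree + 1:
            raise ValueError(
                f"underdetermined: {n} points cannot support a local "
                f"polynomial of degree {degree}"
            )
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]
        self.span = float(span)
        self.degree = int(degree)
        # local window size: at least enough points for the polynomial
        self._k = max(self.degree + 1, int(np.ceil(self.span * n)))

    def _fit_at(self, x0: float) -> float:
        d = np.abs(self.x - x0)
        idx = np.argsort(d, kind="stable")[: self._k]
        xs, ys, ds = self.x[idx], self.y[idx], d[idx]
        dmax = ds.max()
        if dmax == 0.0:
            # all selected points coincide with the query point
            return float(ys.mean())
        w = _tricube(ds / dmax)
        # guard: tricube vanishes at the window edge; keep the system solvable
        if np.count_nonzero(w) <= self.degree:
            w = w + 1e-12
        # design centred at x0 so the intercept is the fitted value
        design = np.vander(xs - x0, N=self.degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], ys * sw, rcond=None)
        return float(coef[0])

    def __call__(self, xq) -> np.ndarray | float:
        xq_arr = np.atleast_1d(np.asarray(xq, dtype=float))
        out = np.array([self._fit_at(x0) for x0 in xq_arr])
        return out if np.ndim(xq) else float(out[0])


def loess_fit(points, span: float = 0.75, degree: int = 2) -> LoessCurve:
    """Fit a loess curve to ``points`` (an iterable of (x, y) pairs).

    Returns a :class:`LoessCurve` evaluable at any x. If the data lie
    exactly on a polynomial of degree <= ``degree``, the curve reproduces
    it for any span, because every local weighted fit interpolates it.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    return LoessCurve(pts[:, 0], pts[:, 1], span=span, degree=degree)
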