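"""Locally weighted polynomial regression (loess).

Classic loess: at each evaluation point the ``span`` fraction of nearest
data points is selected, tricube-weighted by distance, and a local
polynomial (degree 2 by default) is fitted by weighted least squares.  No
robustness iterations are performed (Gaussian family).  Fitted values
cross-validate against R's ``loess(..., degree = 2, surface = "direct")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FittedCurve", "loess_fit", "loess_predict"]


@dataclass
class FittedCurve:
    """A loess curve evaluated on a grid.

    Attributes
    ----------
    x, y : ndarray
        Evaluation positions and fitted values.
    span : float
        Fraction of points in each local neighborhood.
    degree : int
        Local polynomial degree.
    ci95 : (ndarray, ndarray), optional
        Pointwise 95% band (lower, upper), when computed.
    """

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int
    ci95: tuple[np.ndarray, np.ndarray] | None = None

    def __call__(self, xq):
        """Linear interpolation of the fitted curve at query positions."""
        return np.interp(np.asarray(xq, dtype=float), self.x, self.y)


def _local_fit(x, y, x0, h, degree):
    d = np.abs(x - x0)
    if h <= 0:
        # degenerate neighborhood: all selected points coincide with x0
        return float(y[d == d.min()].mean())
    w = np.zeros_like(d)
    inside = d < h
    w[inside] = (1.0 - (d[inside] / h) ** 3) ** 3
    active = w > 0
    if active.sum() <= degree:
        # not enough support for the polynomial; fall back to weighted mean
        return float(np.average(y, weights=w)) if w.sum() > 0 else float(y[np.argmin(d)])
    t = x[active] - x0
    design = np.vander(t, degree + 1, increasing=True)
    sw = np.sqrt(w[active])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y[active] * sw, rcond=None)
    return float(coef[0])


def loess_fit(x, y, span: float, degree: int = 2, xout=None) -> FittedCurve:
    """Fit a loess curve.

    Parameters
    ----------
    x, y : array-like
        Data positions (need not be sorted) and responses.
    span : float
        Neighborhood fraction, 0 < span <= 1; each local fit uses the
        ``floor(span * n)`` nearest points with tricube weights.
    degree : int
        Local polynomial degree (2 reproduces quadratics exactly).
    xout : array-like, optional
        Evaluation grid; defaults to the sorted data positions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    q = int(np.floor(span * n + 1e-9))
    if q < degree + 1:
        raise ValueError(
            f"span {span} selects only {q} of {n} points per local window; "
            f"need at least {degree + 1}"
        )
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if xout is None:
        xq = xs
    else:
        xq = np.atleast_1d(np.asarray(xout, dtype=float))
    fitted = np.empty(xq.size)
    for i, x0 in enumerate(xq):
        d = np.abs(xs - x0)
        h = np.partition(d, q - 1)[q - 1]
        fitted[i] = _local_fit(xs, ys, x0, h, degree)
    return FittedCurve(x=xq, y=fitted, span=span, degree=degree)


def loess_predict(x, y, xq, span: float, degree: int = 2) -> np.ndarray:
    """Fitted loess values at query positions ``xq`` (convenience)."""
    return loess_fit(x, y, span=span, degree=degree, xout=xq).y
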