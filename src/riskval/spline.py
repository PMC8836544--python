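"""Restricted (natural) cubic spline risk functions.

Used to approximate the functional relation between a continuous risk
score and the probability of a cardiac event from a handful of
(score, observed risk) anchor points, when the source publication gives
the relation only graphically.  The basis is the standard
truncated-power natural-spline parameterization: for knots
``t_1 < ... < t_k`` the fitted function is

    f(x) = b0 + b1*x + sum_{j=1..k-2} b_{j+1} * B_j(x)

with

    B_j(x) = [ (x-t_j)_+^3
               - (x-t_{k-1})_+^3 * (t_k-t_j)/(t_k-t_{k-1})
               + (x-t_k)_+^3     * (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

which is linear beyond the boundary knots.  Coefficients are estimated
by least squares on the anchors; evaluation is clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CrsRiskFunction", "rcs_basis", "fit_crs_risk_function"]


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix ``[1, x, B_1(x), ..., B_{k-2}(x)]`` for the
    restricted-cubic-spline basis with the given knots."""
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    k = len(knots)
    if k < 3:
        raise ValueError("at least 3 knots are required")
    t = knots
    scale = (t[-1] - t[0]) ** 2

    def pos3(u: np.ndarray) -> np.ndarray:
        return np.where(u > 0, u, 0.0) ** 3

    cols = [np.ones_like(x), x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass(frozen=True)
class CrsRiskFunction:
    """Fitted score -> event-risk curve; callable, output clipped to [0, 1]."""

    knots: tuple[float, ...]
    coefficients: tuple[float, ...]
    anchors: tuple[tuple[float, float], ...]

    def __call__(self, score) -> np.ndarray | float:
        x = np.asarray(score, dtype=float)
        X = rcs_basis(np.atleast_1d(x), np.asarray(self.knots))
        y = np.clip(X @ np.asarray(self.coefficients), 0.0, 1.0)
        return float(y[0]) if x.ndim == 0 else y


def fit_crs_risk_function(
    anchors: list[tuple[float, float]], knots: list[float]
) -> CrsRiskFunction:
    """Least-squares natural-cubic-spline fit through risk anchors.

    Requires >= 3 distinct anchor scores; duplicate scores with
    conflicting risks are rejected; knots must lie within the anchor
    range.
    """
    seen: dict[float, float] = {}
    for s, r in anchors:
        if s in seen and seen[s] != r:
            raise ValueError(f"conflicting risks for duplicate anchor score {s}")
        seen[s] = r
    xs = np.array(sorted(seen), dtype=float)
    ys = np.array([seen[s] for s in sorted(seen)], dtype=float)
    if len(xs) < 3:
        raise ValueError("at least 3 distinct anchors are required")
    knots_arr = np.sort(np.asarray(knots, dtype=float))
    if knots_arr[0] < xs[0] or knots_arr[-1] > xs[-1]:
        raise ValueError("knots must lie within the anchor range")
    X = rcs_basis(xs, knots_arr)
    coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
    return CrsRiskFunction(
        knots=tuple(knots_arr.tolist()),
        coefficients=tuple(coef.tolist()),
        anchors=tuple((float(s), float(seen[s])) for s in sorted(seen)),
    )
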