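"""Monotone baseline transformations in the Bernstein polynomial basis.

The transformation model for blood loss writes the conditional distribution
as ``logit P(Y <= y | x) = h(y) + x'beta`` with a nondecreasing baseline
``h``.  Here ``h`` is parameterized as a Bernstein polynomial of order ``M``
on a bounded support ``[y_lo, y_hi]``,

    h(y) = sum_k theta_k * b_{k,M}(u),   u = (y - y_lo) / (y_hi - y_lo),

where ``b_{k,M}(u) = C(M,k) u^k (1-u)^{M-k}``.  Nondecreasing coefficients
``theta_0 <= ... <= theta_M`` guarantee a nondecreasing ``h``, which is what
makes the basis attractive for this model class: monotonicity is a linear
constraint on the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = ["BernsteinTransform", "basis_eval", "transform_eval"]

#: tolerance for the nondecreasing-coefficient check
_MONO_TOL = 1e-10


def _scale_to_unit(
    y: np.ndarray, support: tuple[float, float], clamp: bool
) -> np.ndarray:
    lo, hi = support
    u = (np.asarray(y, dtype=float) - lo) / (hi - lo)
    out = (u < 0) | (u > 1)
    if np.any(out):
        if not clamp:
            raise ValueError(
                f"outcome value outside transform support [{lo}, {hi}] "
                "and clamping is disabled"
            )
        warnings.warn(
            f"{int(np.count_nonzero(out))} outcome value(s) outside the "
            f"support [{lo}, {hi}] were clamped",
            RuntimeWarning,
            stacklevel=3,
        )
        u = np.clip(u, 0.0, 1.0)
    return u


def _bern_matrix(u: np.ndarray, order: int) -> np.ndarray:
    """Bernstein design matrix b_{k,order}(u), shape (len(u), order+1)."""
    u = np.atleast_1d(u)[:, None]
    k = np.arange(order + 1)[None, :]
    binom = np.array([comb(order, j) for j in range(order + 1)], dtype=float)
    # 0**0 == 1 under numpy's float power, so endpoints are exact
    return binom * u**k * (1.0 - u) ** (order - k)


def basis_eval(
    order: int,
    support: tuple[float, float],
    y: float | np.ndarray,
    derivative: bool = False,
    clamp: bool = False,
) -> np.ndarray:
    """Evaluate the Bernstein basis (or its y-derivative) at outcome values.

    Parameters
    ----------
    order : int
        Polynomial order M (>= 0); the basis has M+1 elements.
    support : (float, float)
        Outcome interval [y_lo, y_hi] mapped to the unit interval.
    y : float or array
        Outcome value(s).
    derivative : bool
        If True, return d b_{k,M}/dy; the chain rule contributes a factor
        1/(y_hi - y_lo).
    clamp : bool
        Clamp y outside the support to the endpoints (with a warning)
        instead of raising.

    Returns
    -------
    ndarray of shape (order+1,) for scalar y, else (len(y), order+1).
    """
    if order < 0:
        raise ValueError("order must be nonnegative")
    lo, hi = support
    if not lo < hi:
        raise ValueError("support must satisfy y_lo < y_hi")
    scalar = np.isscalar(y) or np.ndim(y) == 0
    u = _scale_to_unit(y, support, clamp)
    if not derivative:
        B = _bern_matrix(u, order)
    else:
        # d b_{k,M}/du = M * (b_{k-1,M-1} - b_{k,M-1})
        B = np.zeros((np.atleast_1d(u).size, order + 1))
        if order >= 1:
            low = _bern_matrix(u, order - 1)
            B[:, 1:] += order * low
            B[:, :-1] -= order * low
        B /= hi - lo
    return B[0] if scalar else B


@dataclass(frozen=True)
class BernsteinTransform:
    """A monotone nondecreasing Bernstein-basis transformation h(y).

    Attributes
    ----------
    order : int
        Polynomial order M.
    support : (float, float)
        Interval [y_lo, y_hi] on which h is defined; h(y_lo) = theta[0],
        h(y_hi) = theta[-1].
    theta : ndarray, shape (order+1,)
        Nondecreasing basis coefficients.
    """

    order: int
    support: tuple[float, float]
    theta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "support", (float(self.support[0]), float(self.support[1])))
        if self.support[0] >= self.support[1]:
            raise ValueError("support must satisfy y_lo < y_hi")
        if theta.shape != (self.order + 1,):
            raise ValueError(
                f"theta must have length order+1 = {self.order + 1}, "
                f"got {theta.shape}"
            )
        if np.any(np.diff(theta) < -_MONO_TOL):
            raise ValueError("theta must be nondecreasing (monotone h)")

    def __call__(
        self, y: float | np.ndarray, derivative: bool = False, clamp: bool = False
    ) -> float | np.ndarray:
        return transform_eval(self, y, derivative=derivative, clamp=clamp)

    def inverse(self, z: float | np.ndarray, grid_size: int = 4096) -> float | np.ndarray:
        """h^{-1}(z) by monotone interpolation on a dense grid.

        Values of z outside [h(y_lo), h(y_hi)] map to the support endpoints.
        """
        lo, hi = self.support
        grid = np.linspace(lo, hi, grid_size)
        hz = transform_eval(self, grid)
        # np.interp requires strictly increasing xp only for correctness of
        # interior lookup; flat stretches of h resolve to their left edge.
        out = np.interp(z, hz, grid, left=lo, right=hi)
        return float(out) if np.ndim(z) == 0 else out


def transform_eval(
    t: BernsteinTransform,
    y: float | np.ndarray,
    derivative: bool = False,
    clamp: bool = False,
) -> float | np.ndarray:
    """Evaluate h(y) or h'(y) for a Bernstein transform.

    The derivative uses the lower-order identity

        h'(y) = M/(y_hi - y_lo) * sum_k (theta_{k+1} - theta_k) b_{k,M-1}(u)

    which is nonnegative whenever theta is nondecreasing.
    """
    scalar = np.isscalar(y) or np.ndim(y) == 0
    lo, hi = t.support
    if not derivative:
        B = basis_eval(t.order, t.support, y, clamp=clamp)
        val = B @ t.theta if not scalar else float(B @ t.theta)
        return val
    if t.order == 0:
        return 0.0 if scalar else np.zeros(np.atleast_1d(y).size)
    u = _scale_to_unit(y, t.support, clamp)
    low = _bern_matrix(u, t.order - 1)
    val = (t.order / (hi - lo)) * (low @ np.diff(t.theta))
    return float(val[0]) if scalar else val
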