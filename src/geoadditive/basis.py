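"""Penalized B-spline machinery for the nonlinear age effect.

The smooth age effect f(z) is expanded in a B-spline basis on an
equidistant knot grid over the observed age range: with ``n_knots`` knots
spanning [z_min, z_max] there are m = n_knots - 1 interior intervals and
J = m + degree basis functions.  The Bayesian P-spline prior is a
second-order random walk on the coefficients, whose precision (up to the
smoothing variance) is the second-difference penalty matrix returned by
:func:`rw2_penalty`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


def rw2_penalty(n_basis: int) -> np.ndarray:
    """Second-order random-walk penalty K = D2' D2 for J coefficients.

    The quadratic form theta' K theta equals the sum of squared second
    differences of theta; K is symmetric positive semidefinite with rank
    J - 2 (its null space is spanned by constant and linear trends).
    """
    if n_basis < 3:
        raise ValueError("RW2 penalty needs at least 3 basis functions")
    d2 = np.diff(np.eye(n_basis), n=2, axis=0)
    return d2.T @ d2


@dataclass(frozen=True)
class SplineBasis:
    """Equidistant B-spline basis on a fixed age range."""

    z_min: float
    z_max: float
    n_knots: int = 20
    degree: int = 3

    def __post_init__(self):
        if self.n_knots < self.degree + 1:
            raise ValueError("need n_knots >= degree + 1")
        if not self.z_max > self.z_min:
            raise ValueError("need z_max > z_min")

    @property
    def n_basis(self) -> int:
        # J = m + l with m interior intervals, l the degree
        return self.n_knots - 1 + self.degree

    @property
    def inner_knots(self) -> np.ndarray:
        return np.linspace(self.z_min, self.z_max, self.n_knots)

    @property
    def full_knots(self) -> np.ndarray:
        """Knot vector extended equidistantly by ``degree`` knots per side."""
        h = (self.z_max - self.z_min) / (self.n_knots - 1)
        left = self.z_min - h * np.arange(self.degree, 0, -1)
        right = self.z_max + h * np.arange(1, self.degree + 1)
        return np.concatenate([left, self.inner_knots, right])

    def design_matrix(self, z, on_outside: str = "raise") -> np.ndarray:
        """Evaluate the J basis functions at each z (rows sum to one).

        ``on_outside`` controls values beyond [z_min, z_max]: ``"raise"``
        (the fitting default, keeping the penalty interpretation intact) or
        ``"clamp"`` (prediction convenience; values are pinned to the range
        boundary).
        """
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite values in spline input")
        outside = (z < self.z_min) | (z > self.z_max)
        if np.any(outside):
            if on_outside == "clamp":
                z = np.clip(z, self.z_min, self.z_max)
            else:
                bad = z[outside][0]
                raise ValueError(
                    f"value {bad} outside spline range [{self.z_min}, {self.z_max}]"
                )
        mat = BSpline.design_matrix(z, self.full_knots, self.degree).toarray()
        return mat

    def penalty(self) -> np.ndarray:
        return rw2_penalty(self.n_basis)

    def penalty_rank(self) -> int:
        return self.n_basis - 2
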