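"""Exact Pólya–Gamma PG(1, z) sampling.

The logit data augmentation used by the MCMC backend needs one PG(1, z)
draw per record per category sweep.  A PG(1, z) variable is J*(1, z/2)/4,
where J* is the tilted Jacobi variable of Devroye's alternating-series
rejection sampler; the sampler below follows that construction (mixture of
a truncated inverse-Gaussian body and an exponential tail, series
acceptance test) and is exact, not a truncated-sum approximation.

Everything is numba-compiled; the module keeps its own RNG stream (numba's
internal one), seeded explicitly via :func:`seed_pg` so MCMC runs are
reproducible.
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series/tail switch point of the J* density


@njit(cache=True, fastmath=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True, fastmath=True)
def _pigauss(x, z):
    """CDF at x of an inverse-Gaussian with mean 1/z, shape 1 (z >= 0)."""
    rx = 1.0 / math.sqrt(x)
    out = _norm_cdf(rx * (x * z - 1.0))
    # guard the exp(2z) factor; for moderate z the second term underflows anyway
    b = -rx * (x * z + 1.0)
    if b > -37.0:
        out += math.exp(2.0 * z) * _norm_cdf(b)
    return out


@njit(cache=True, fastmath=True)
def _rtinvgauss(z, t):
    """Draw inverse-Gaussian(mean 1/z, shape 1) truncated to (0, t]."""
    x = t + 1.0
    if z < 1.0 / t:
        # mean exceeds t: sample 1/X via truncated chi-square trick, then
        # thin by the exp(-z^2 x / 2) tilt
        while True:
            while True:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) ** 2)
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
        return x
    return x


@njit(cache=True, fastmath=True)
def _series_coef(n, x, t):
    """n-th coefficient a_n(x) of Devroye's alternating series."""
    np5 = n + 0.5
    if x <= t:
        return math.pi * np5 * (2.0 / (math.pi * x)) ** 1.5 * math.exp(
            -2.0 * np5 * np5 / x
        )
    return math.pi * np5 * math.exp(-0.5 * np5 * np5 * math.pi * math.pi * x)


@njit(cache=True, fastmath=True)
def _pg1_single(zin):
    """One exact PG(1, z) draw."""
    z = 0.5 * abs(zin)
    t = _TRUNC
    k = 0.125 * math.pi * math.pi + 0.5 * z * z
    # mixture masses of the exponential tail and inverse-Gaussian body
    p = 0.5 * math.pi / k * math.exp(-k * t)
    q = 2.0 * math.exp(-z) * _pigauss(t, z)
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = t - math.log(np.random.random()) / k
        else:
            x = _rtinvgauss(z, t)
        s = _series_coef(0, x, t)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _series_coef(n, x, t)
                if y <= s:
                    return 0.25 * x
            else:
                s += _series_coef(n, x, t)
                if y > s:
                    break


@njit(cache=True, fastmath=True)
def seed_pg(seed):
    """Seed the numba-internal RNG stream used by the PG sampler."""
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def pg_draw(z):
    """Vector of independent PG(1, z_i) draws for a 1-d array z."""
    n = z.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = _pg1_single(z[i])
    return out


def pg_mean(z):
    """Analytic E[PG(1, z)] = tanh(z/2) / (2 z), with the z -> 0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out


def pg_var(z):
    """Analytic Var[PG(1, z)]; the z -> 0 limit is 1/24."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 1.0 / 24.0)
    nz = np.abs(z) > 1e-4
    zz = z[nz]
    out[nz] = (np.sinh(zz) - zz) / (4.0 * zz**3 * np.cosh(zz / 2.0) ** 2)
    return out
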