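"""Pólya-Gamma PG(1, z) random variates.

Exact Devroye-type alternating-series sampler for the Jacobi J*(1, z)
distribution, of which PG(1, z) is a rescaling: PG(1, z) = J*(1, z/2) / 4.
Used for the data-augmentation step of the logistic Gibbs sampler, where one
PG draw is needed per Bernoulli observation per sweep; the hot loop is
compiled with numba.

The numba-internal RNG state is used; call :func:`seed_pg` before a chain to
make draws reproducible.
"""

from __future__ import annotations

import math

import numba
import numpy as np

# Truncation point of the two-piece proposal (Devroye's t).
_TRUNC = 0.64


@numba.njit(cache=True)
def _pnorm(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@numba.njit(cache=True)
def _mass_texpon(z: float) -> float:
    """P(proposal falls in the exponential tail piece), i.e. p / (p + q)."""
    t = _TRUNC
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + math.log(_pnorm(b))
    xa = x0 + z + math.log(_pnorm(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@numba.njit(cache=True)
def _rtigauss(z: float) -> float:
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    t = _TRUNC
    z = abs(z)
    mu = 1.0e12 if z < 1.0e-12 else 1.0 / z
    x = t + 1.0
    if mu > t:
        # Sample via reciprocal-chi2 proposal with exp(-z^2 x / 2) thinning.
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = -math.log(np.random.random())
            e2 = -math.log(np.random.random())
            while e1 * e1 > 2.0 * e2 / t:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        # Plain IG sampling, rejecting draws beyond t.
        while x > t:
            y = np.random.normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@numba.njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    """n-th alternating-series coefficient a_n(x) of the J*(1,.) density."""
    t = _TRUNC
    npd = n + 0.5
    if x > t:
        return math.pi * npd * math.exp(-npd * npd * math.pi * math.pi * x / 2.0)
    return (
        math.pow(2.0 / (math.pi * x), 1.5)
        * math.pi
        * npd
        * math.exp(-2.0 * npd * npd / x)
    )


@numba.njit(cache=True)
def _pg_draw_one(c: float) -> float:
    """One exact draw from PG(1, c)."""
    z = abs(c) / 2.0
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC - math.log(np.random.random()) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x / 4.0
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@numba.njit(cache=True)
def pg_draw(c: np.ndarray, out: np.ndarray) -> None:
    """Fill ``out`` with PG(1, c[j]) draws, elementwise."""
    for j in range(c.shape[0]):
        out[j] = _pg_draw_one(c[j])


@numba.njit(cache=True)
def seed_pg(seed: int) -> None:
    """Seed the numba-internal RNG used by the PG draws."""
    np.random.seed(seed)


def pg_mean(c: np.ndarray | float) -> np.ndarray | float:
    """Analytic E[PG(1, c)] = tanh(c/2) / (2c), with the c→0 limit 1/4."""
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, 0.25)
    nz = np.abs(c) > 1e-8
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    return out if out.shape else float(out)
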