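"""Fixed-step RK4 kernels for the within-well logistic system.

The hot loop (96 wells x thousands of steps x thousands of runs) is
compiled with numba when available; a NumPy fallback keeps the package
importable without it.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _rk4_wells_kernel(x0, rates, K, t, dt_max):  # pragma: no cover - numba
    """Integrate dx_i/dt = x_i R_i (1 - sum_k x_k / K) for each well.

    x0, rates: (n_wells, 4) arrays. The step is shrunk so an integer
    number of steps covers t exactly. Returns (final states, ok flag);
    ok is False if any density went negative beyond tolerance.
    """
    n, ns = x0.shape
    out = x0.copy()
    nsteps = max(1, int(math.ceil(t / dt_max - 1e-12)))
    dt = t / nsteps
    ok = True
    k1 = np.empty(ns)
    k2 = np.empty(ns)
    k3 = np.empty(ns)
    k4 = np.empty(ns)
    xt = np.empty(ns)
    for w in range(n):
        x = out[w]
        r = rates[w]
        for _ in range(nsteps):
            tot = 0.0
            for i in range(ns):
                tot += x[i]
            b = 1.0 - tot / K
            for i in range(ns):
                k1[i] = x[i] * r[i] * b

            tot = 0.0
            for i in range(ns):
                xt[i] = x[i] + 0.5 * dt * k1[i]
                tot += xt[i]
            b = 1.0 - tot / K
            for i in range(ns):
                k2[i] = xt[i] * r[i] * b

            tot = 0.0
            for i in range(ns):
                xt[i] = x[i] + 0.5 * dt * k2[i]
                tot += xt[i]
            b = 1.0 - tot / K
            for i in range(ns):
                k3[i] = xt[i] * r[i] * b

            tot = 0.0
            for i in range(ns):
                xt[i] = x[i] + dt * k3[i]
                tot += xt[i]
            b = 1.0 - tot / K
            for i in range(ns):
                k4[i] = xt[i] * r[i] * b

            for i in range(ns):
                x[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                if x[i] < -1e-9:
                    ok = False
                elif x[i] < 0.0:
                    x[i] = 0.0
    return out, ok


def _rk4_wells_numpy(x0, rates, K, t, dt_max):
    """Vectorised NumPy twin of the numba kernel (fallback / cross-check)."""
    x = np.array(x0, dtype=float)
    r = np.asarray(rates, dtype=float)
    nsteps = max(1, int(math.ceil(t / dt_max - 1e-12)))
    dt = t / nsteps

    def f(y):
        b = 1.0 - y.sum(axis=-1, keepdims=True) / K
        return y * r * b

    ok = True
    for _ in range(nsteps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (x < -1e-9).any():
            ok = False
        np.clip(x, 0.0, None, out=x)
    return x, ok


def rk4_wells(x0, rates, K, t, dt_max):
    """Dispatch to the compiled kernel when numba is present."""
    x0 = np.ascontiguousarray(x0, dtype=np.float64)
    rates = np.ascontiguousarray(rates, dtype=np.float64)
    if _HAVE_NUMBA:
        return _rk4_wells_kernel(x0, rates, float(K), float(t), float(dt_max))
    return _rk4_wells_numpy(x0, rates, K, t, dt_max)
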