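"""Cubic-spline envelope kernels for the sifting loop.

Sifting evaluates two natural cubic splines (upper/lower envelope through
the local extrema) per iteration, thousands of times per recording, so the
extrema scan, the tridiagonal spline solve, and the evaluation are compiled
with numba. ``envelope_mean_numpy`` is an independent SciPy-based reference
kept for cross-checking the compiled path.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _local_extrema(x):
    """Indices of strict local maxima and minima; plateau centres count once.

    Returns (max_idx, min_idx) as int64 arrays.
    """
    n = x.shape[0]
    max_idx = np.empty(n, dtype=np.int64)
    min_idx = np.empty(n, dtype=np.int64)
    nmax = 0
    nmin = 0
    # track the index where the last nonzero slope started, to place
    # plateau extrema at the plateau centre
    prev_slope = 0  # -1, 0, +1
    plateau_start = 0
    for i in range(1, n):
        d = x[i] - x[i - 1]
        s = 0
        if d > 0.0:
            s = 1
        elif d < 0.0:
            s = -1
        if s == 0:
            continue
        if prev_slope == 1 and s == -1:
            j = (plateau_start + i - 1) // 2 if x[plateau_start] == x[i - 1] else i - 1
            max_idx[nmax] = j
            nmax += 1
        elif prev_slope == -1 and s == 1:
            j = (plateau_start + i - 1) // 2 if x[plateau_start] == x[i - 1] else i - 1
            min_idx[nmin] = j
            nmin += 1
        prev_slope = s
        plateau_start = i
    return max_idx[:nmax], min_idx[:nmin]


@njit(cache=True)
def _natural_spline_coeffs(t, y):
    """Second derivatives of the natural cubic spline through (t, y).

    Thomas-algorithm solve of the standard tridiagonal system; natural
    boundary conditions (zero curvature at both ends).
    """
    n = t.shape[0]
    m = np.zeros(n)
    if n < 3:
        return m
    # sub/diag/super for interior equations
    a = np.empty(n - 2)
    b = np.empty(n - 2)
    c = np.empty(n - 2)
    d = np.empty(n - 2)
    for i in range(1, n - 1):
        h0 = t[i] - t[i - 1]
        h1 = t[i + 1] - t[i]
        a[i - 1] = h0
        b[i - 1] = 2.0 * (h0 + h1)
        c[i - 1] = h1
        d[i - 1] = 6.0 * ((y[i + 1] - y[i]) / h1 - (y[i] - y[i - 1]) / h0)
    # forward sweep
    for i in range(1, n - 2):
        w = a[i] / b[i - 1]
        b[i] -= w * c[i - 1]
        d[i] -= w * d[i - 1]
    # back substitution
    m[n - 2] = d[n - 3] / b[n - 3]
    for i in range(n - 4, -1, -1):
        m[i + 1] = (d[i] - c[i] * m[i + 2]) / b[i]
    return m


@njit(cache=True)
def _spline_eval_grid(t, y, m, nq):
    """Evaluate the spline with knot 2nd-derivatives m at 0, 1, ..., nq-1.

    Knots t are strictly increasing and bracket [0, nq-1]; query points
    outside the knot span are linearly extrapolated from the end cubics
    (does not occur with mirrored-extrema padding).
    """
    out = np.empty(nq)
    nk = t.shape[0]
    k = 0
    for q in range(nq):
        xq = float(q)
        while k < nk - 2 and t[k + 1] < xq:
            k += 1
        h = t[k + 1] - t[k]
        A = (t[k + 1] - xq) / h
        B = (xq - t[k]) / h
        out[q] = (
            A * y[k]
            + B * y[k + 1]
            + ((A * A * A - A) * m[k] + (B * B * B - B) * m[k + 1]) * h * h / 6.0
        )
    return out


@njit(cache=True)
def _mirror_knots(idx, val, n):
    """Pad extrema with 2 mirror-reflected points at each record end."""
    k = idx.shape[0]
    npad = 2 if k >= 2 else 1
    t = np.empty(k + 2 * npad)
    v = np.empty(k + 2 * npad)
    for j in range(npad):
        # reflect about t=0: -idx[npad-1-j]; keep strictly increasing order
        t[j] = -float(idx[npad - 1 - j])
        v[j] = val[npad - 1 - j]
    for j in range(k):
        t[npad + j] = float(idx[j])
        v[npad + j] = val[j]
    for j in range(npad):
        t[npad + k + j] = 2.0 * (n - 1) - float(idx[k - 1 - j])
        v[npad + k + j] = val[k - 1 - j]
    # mirrored point may coincide with an end extremum at the boundary;
    # nudge duplicates apart to keep the spline system nonsingular
    for j in range(1, t.shape[0]):
        if t[j] <= t[j - 1]:
            t[j] = t[j - 1] + 0.5
    return t, v


@njit(cache=True)
def envelope_mean(x):
    """Mean of the upper and lower cubic-spline envelopes of x.

    Returns (mean_envelope, n_maxima, n_minima); the mean envelope is valid
    only when both counts are >= 2 (otherwise the residue is monotone-like
    and sifting must stop).
    """
    n = x.shape[0]
    max_idx, min_idx = _local_extrema(x)
    if max_idx.shape[0] < 2 or min_idx.shape[0] < 2:
        return np.zeros(n), max_idx.shape[0], min_idx.shape[0]
    tu, vu = _mirror_knots(max_idx, x[max_idx], n)
    tl, vl = _mirror_knots(min_idx, x[min_idx], n)
    mu = _natural_spline_coeffs(tu, vu)
    ml = _natural_spline_coeffs(tl, vl)
    upper = _spline_eval_grid(tu, vu, mu, n)
    lower = _spline_eval_grid(tl, vl, ml, n)
    return 0.5 * (upper + lower), max_idx.shape[0], min_idx.shape[0]


def envelope_mean_numpy(x: np.ndarray):
    """SciPy reference implementation of :func:`envelope_mean`.

    Same extrema rule, mirroring, and natural-spline boundary condition;
    used in tests as an independent check on the compiled kernel.
    """
    from scipy.interpolate import CubicSpline

    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    max_idx, min_idx = _local_extrema(x)
    if len(max_idx) < 2 or len(min_idx) < 2:
        return np.zeros(n), len(max_idx), len(min_idx)

    def env(idx):
        t, v = _mirror_knots(idx, x[idx], n)
        return CubicSpline(t, v, bc_type="natural")(np.arange(n))

    return 0.5 * (env(max_idx) + env(min_idx)), len(max_idx), len(min_idx)
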