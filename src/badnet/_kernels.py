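"""Numba-compiled fixed-step RK4 kernels.

The 13-species right-hand side here must stay numerically identical to the
readable reference implementation :func:`badnet.model_core.rhs`; the test
suite cross-checks the two (and both against scipy's adaptive integrator).
Inputs are pre-resolved per schedule segment: ``veff`` already carries the
``1/(1+u)`` inhibition factors and ``dvec[11]`` the BADS112A-scaled
pS112-BAD dephosphorylation rate.
"""

import numpy as np
from numba import njit

# status codes returned by the integrators
OK = 0
NONFINITE = 1
NEGATIVE = 2

#: tolerated negative excursion: anything in (-1e-9, 0) is float noise and
#: clipped to 0; below that the step is treated as an integration failure.
NEG_TOL = -1e-9


@njit(cache=True)
def _rhs13(y, t, veff, km, hn, dvec, alpha, egf, stress, dy):
    for j in range(13):
        dy[j] = 0.0

    # activation terms: V * u^n / (K^n + u^n)
    def _hill(i, u):
        if u <= 0.0:
            return 0.0
        un = u ** hn[i]
        return veff[i] * un / (km[i] ** hn[i] + un)

    dy[0] = _hill(0, egf) - dvec[0] * t * y[0]
    dy[1] = _hill(1, y[0]) - dvec[1] * t * y[1]
    dy[2] = _hill(2, y[1]) - dvec[2] * t * y[2]
    dy[3] = _hill(3, y[2]) - dvec[3] * t * y[3]
    dy[4] = _hill(4, egf) - dvec[4] * y[4]
    dy[5] = _hill(5, y[4]) - dvec[5] * y[5]
    dy[6] = _hill(6, 1.0) - dvec[6] * y[6]
    dy[7] = _hill(7, y[6]) - dvec[7] * y[7]
    dy[8] = _hill(8, stress) - dvec[8] * y[8]
    dy[9] = _hill(9, y[8]) - dvec[9] * y[9]
    dy[10] = _hill(10, y[9]) - dvec[10] * y[10]
    s112_drive = y[3] + y[9] + ((1.0 - alpha) + alpha * y[7])
    dy[11] = _hill(11, s112_drive) - dvec[11] * y[11]
    dy[12] = _hill(12, y[5]) + _hill(13, y[7]) - dvec[12] * y[12]


@njit(cache=True)
def integrate_segment(y0, t0, dt, nsteps, veff, km, hn, dvec, alpha, egf, stress, out):
    """RK4 over one constant-input segment; ``out`` is (nsteps+1, 13).

    Returns (status, t_fail). States are clipped at 0 for sub-NEG_TOL-sized
    negative excursions; larger ones or non-finite values abort.
    """
    y = y0.copy()
    k1 = np.empty(13)
    k2 = np.empty(13)
    k3 = np.empty(13)
    k4 = np.empty(13)
    yt = np.empty(13)
    out[0, :] = y
    t = t0
    for s in range(nsteps):
        _rhs13(y, t, veff, km, hn, dvec, alpha, egf, stress, k1)
        for j in range(13):
            yt[j] = max(y[j] + 0.5 * dt * k1[j], 0.0)
        _rhs13(yt, t + 0.5 * dt, veff, km, hn, dvec, alpha, egf, stress, k2)
        for j in range(13):
            yt[j] = max(y[j] + 0.5 * dt * k2[j], 0.0)
        _rhs13(yt, t + 0.5 * dt, veff, km, hn, dvec, alpha, egf, stress, k3)
        for j in range(13):
            yt[j] = max(y[j] + dt * k3[j], 0.0)
        _rhs13(yt, t + dt, veff, km, hn, dvec, alpha, egf, stress, k4)
        for j in range(13):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        t = t0 + (s + 1) * dt
        for j in range(13):
            if not np.isfinite(y[j]):
                return NONFINITE, t
            if y[j] < 0.0:
                if y[j] > NEG_TOL:
                    y[j] = 0.0
                else:
                    return NEGATIVE, t
        out[s + 1, :] = y
    return OK, t


@njit(cache=True)
def apoptosis_integrate(times, g, k_a):
    """RK4 for ``dC/dt = k_a * t * (100 - C) * g(t)`` on the trajectory grid.

    ``g`` is the combined anti-apoptotic inhibition factor sampled at
    ``times`` (linearly interpolated at half-steps); C is clipped to
    [0, 100] and the rate vanishes at the cap.
    """
    m = times.shape[0]
    out = np.empty(m)
    c = 0.0
    out[0] = 0.0
    for i in range(m - 1):
        h = times[i + 1] - times[i]
        t0 = times[i]
        tm = t0 + 0.5 * h
        gm = 0.5 * (g[i] + g[i + 1])

        r1 = k_a * t0 * (100.0 - c) * g[i] if c < 100.0 else 0.0
        c1 = min(c + 0.5 * h * r1, 100.0)
        r2 = k_a * tm * (100.0 - c1) * gm if c1 < 100.0 else 0.0
        c2 = min(c + 0.5 * h * r2, 100.0)
        r3 = k_a * tm * (100.0 - c2) * gm if c2 < 100.0 else 0.0
        c3 = min(c + h * r3, 100.0)
        r4 = k_a * times[i + 1] * (100.0 - c3) * g[i + 1] if c3 < 100.0 else 0.0

        c = c + h / 6.0 * (r1 + 2.0 * r2 + 2.0 * r3 + r4)
        if c > 100.0:
            c = 100.0
        if c < 0.0:
            c = 0.0
        out[i + 1] = c
    return out
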