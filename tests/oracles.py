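"""Independent reference computations used by the test suite.

These deliberately avoid the code paths they check: the DFT coefficient via
numpy's FFT, ordinary least squares via explicit closed-form formulas (with
the t distribution entered only through scipy.special), and the smoothing
spline via scipy's independent `make_smoothing_spline` solver.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.interpolate import make_smoothing_spline


def dft_coefficient(y: np.ndarray, f: float, sample_rate: float) -> complex:
    """2/N times the DFT bin at ``f`` (requires integer cycles)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    k = f * n / sample_rate
    assert abs(k - round(k)) < 1e-9, "frequency must land on a DFT bin"
    x = np.fft.rfft(y)[int(round(k))]
    return 2.0 / n * x


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple-regression statistics from textbook formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = np.sum(resid**2)
    sst = np.sum((y - ym) ** 2)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    df = n - 2
    se = np.sqrt(sse / df / sxx) if df > 0 else np.nan
    if se == 0:
        t, p = np.inf, 0.0
    else:
        t = slope / se
        p = 2.0 * special.stdtr(df, -abs(t))
    tcrit = special.stdtrit(df, 0.975)
    return {
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "p_value": p,
        "ci_low": slope - tcrit * se,
        "ci_high": slope + tcrit * se,
        "n": n,
    }


def spline_oracle(x, y, w, smoothing: float):
    """Same objective as the package's fit, solved by scipy's independent
    smoothing-spline implementation (p*misfit + (1-p)*roughness with
    lam = (1-p)/p)."""
    return make_smoothing_spline(
        np.asarray(x, float), np.asarray(y, float), w=np.asarray(w, float),
        lam=(1.0 - smoothing) / smoothing,
    )
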