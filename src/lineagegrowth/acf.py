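"""Autocorrelation estimator shared by the generation- and time-scale analyses.

The plug-in estimator

    ACF(k) = 1 / ((N - k) sigma^2) * sum_n (X_n - mu)(X_{n+k} - mu)

uses the global mean and SD of the series (not per-lag demeaning), so
ACF(0) = 1 exactly when sigma^2 is the population (ddof=0) variance.
For continuous series, lags in steps are mapped to hours through
xcal = median(delta t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcfResult", "autocorrelation"]


@dataclass
class AcfResult:
    lags: np.ndarray            # integer step (or generation) lags
    lag_times: np.ndarray       # lags * xcal; equal to lags when xcal == 1
    coefficients: np.ndarray
    n_per_lag: np.ndarray
    mu: float
    sigma: float
    xcal: float                 # time per step; 1.0 for generation series

    def __getitem__(self, k: int) -> float:
        return float(self.coefficients[int(k)])


def autocorrelation(values: np.ndarray, max_lag: int, xcal: float = 1.0) -> AcfResult:
    """Autocorrelation of ``values`` at integer lags 0..max_lag."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    if max_lag >= n:
        import warnings
        warnings.warn(f"max_lag {max_lag} >= series length {n}; truncating")
        max_lag = n - 1
    mu = float(x.mean())
    sigma2 = float(x.var(ddof=0))
    if sigma2 == 0.0:
        raise ValueError("series has zero variance")
    xc = x - mu
    lags = np.arange(max_lag + 1)
    coeffs = np.empty(max_lag + 1)
    counts = np.empty(max_lag + 1, dtype=int)
    for k in lags:
        prods = xc[: n - k] * xc[k:]
        coeffs[k] = prods.sum() / ((n - k) * sigma2)
        counts[k] = n - k
    return AcfResult(lags=lags, lag_times=lags * xcal, coefficients=coeffs,
                     n_per_lag=counts, mu=mu, sigma=float(np.sqrt(sigma2)), xcal=xcal)
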