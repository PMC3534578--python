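"""Time-series features for pause-kinetics classification.

From one replicate's (R, P, E) triple — RNA numbers, protein numbers and
cumulative protein numbers sampled at 1 s — ten summary statistics are
computed:

1-2   lag-weighted mean / SD of the autocorrelation function of R
3-4   lag-weighted mean / SD of the autocorrelation function of P
5-6   lag-weighted mean / SD of the cross-correlation of (R, P)
7-8   lag-weighted mean / SD of the cross-correlation of (P, E)
9-10  mean / SD of the RNA "decay times" (lengths of maximal runs of
      consecutive steps over which R does not increase)

The correlation summaries weight the lag-l correlation by l before
averaging, i.e. m = (1/K) sum_l r(l)*l and the matching (K-1)-normalised
SD.  This lag weighting is part of the statistic's definition and is kept
exactly as defined (an unweighted mean is *not* equivalent).
The default maximum lag is K = 300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "autocorr",
    "autocorr_function",
    "crosscorr",
    "crosscorr_function",
    "corr_summary",
    "decay_times",
    "feature_vector",
    "feature_table",
    "z_transform",
    "DegenerateSeriesError",
]

FEATURE_NAMES = (
    "m_acf_R", "s_acf_R",
    "m_acf_P", "s_acf_P",
    "m_ccf_RP", "s_ccf_RP",
    "m_ccf_PE", "s_ccf_PE",
    "m_decay_R", "s_decay_R",
)


class DegenerateSeriesError(ValueError):
    """A constant (zero-variance) series where correlation is undefined."""


@dataclass(frozen=True)
class FeatureVector:
    """The 10 classification features of one replicate (see module docs)."""

    values: tuple[float, ...]
    model_label: str = ""
    replicate: int = -1

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError("feature vector must have exactly 10 entries")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _centered(x) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least 2 points")
    xc = x - x.mean()
    ss = float(np.dot(xc, xc))
    if ss == 0.0:
        raise DegenerateSeriesError("constant series: correlation undefined")
    return xc, ss


def autocorr(series, lag: int) -> float:
    """Lag-l sample autocorrelation, normalised by the full sum of squares."""
    xc, ss = _centered(series)
    T = xc.size
    if not 0 <= lag < T - 1:
        raise ValueError("lag must satisfy 0 <= lag < T-1")
    if lag == 0:
        return 1.0
    return float(np.dot(xc[lag:], xc[:-lag]) / ss)


def autocorr_function(series, max_lag: int) -> np.ndarray:
    """Autocorrelation at lags 1..max_lag (FFT-based, same normalisation)."""
    xc, ss = _centered(series)
    if max_lag >= xc.size - 1:
        raise ValueError("max_lag must be < T-1")
    # statsmodels' acf with adjusted=False matches the estimator exactly.
    r = _sm_acf(np.asarray(series, float), nlags=max_lag, fft=True, adjusted=False)
    return np.asarray(r[1:], dtype=float)


def crosscorr(x, y, lag: int) -> float:
    """Lag-l sample cross-correlation of x with y lagged behind by l."""
    xc, ssx = _centered(x)
    yc, ssy = _centered(y)
    if xc.size != yc.size:
        raise ValueError("series must share length")
    T = xc.size
    if not 0 <= lag < T - 1:
        raise ValueError("lag must satisfy 0 <= lag < T-1")
    if lag == 0:
        num = float(np.dot(xc, yc))
    else:
        num = float(np.dot(xc[lag:], yc[:-lag]))
    return num / np.sqrt(ssx * ssy)


def crosscorr_function(x, y, max_lag: int) -> np.ndarray:
    """Cross-correlation at lags 1..max_lag."""
    xc, ssx = _centered(x)
    yc, ssy = _centered(y)
    if xc.size != yc.size:
        raise ValueError("series must share length")
    if max_lag >= xc.size - 1:
        raise ValueError("max_lag must be < T-1")
    denom = np.sqrt(ssx * ssy)
    out = np.empty(max_lag, dtype=float)
    for l in range(1, max_lag + 1):
        out[l - 1] = np.dot(xc[l:], yc[:-l]) / denom
    return out


def corr_summary(corr_values) -> tuple[float, float]:
    """Lag-weighted mean and SD of a correlation function r(1..K).

    m = (1/K) * sum_l r(l)*l ;  s = sqrt( (1/(K-1)) * sum_l (r(l)*l - m)^2 ).
    """
    r = np.asarray(corr_values, dtype=float)
    K = r.size
    if K < 2:
        raise ValueError("need at least K=2 correlation values")
    weighted = r * np.arange(1, K + 1)
    m = float(weighted.sum() / K)
    s = float(np.sqrt(np.sum((weighted - m) ** 2) / (K - 1)))
    return m, s


def decay_times(series) -> np.ndarray:
    """Lengths of maximal runs of consecutive steps with x[t-1] >= x[t].

    Each run length counts the number of consecutive non-increasing steps;
    an empty array is returned for a strictly increasing series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    nonincr = x[:-1] >= x[1:]
    runs: list[int] = []
    count = 0
    for flag in nonincr:
        if flag:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return np.asarray(runs, dtype=float)


def _decay_summary(series) -> tuple[float, float]:
    d = decay_times(series)
    if d.size == 0:
        return 0.0, 0.0  # convention for pathological (never-decaying) input
    m = float(d.mean())
    s = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return m, s


def feature_vector(R_row, P_row, E_row, K: int = 300,
                   model_label: str = "", replicate: int = -1) -> FeatureVector:
    """Assemble the 10-feature vector from one (R, P, E) replicate triple."""
    R = np.asarray(R_row, dtype=float)
    P = np.asarray(P_row, dtype=float)
    E = np.asarray(E_row, dtype=float)
    if not (R.size == P.size == E.size):
        raise ValueError("R, P, E rows must share length")
    if R.size < K + 2:
        raise ValueError(f"rows must have length >= K+2 = {K + 2}")

    def guarded(fn, name):
        try:
            return fn()
        except DegenerateSeriesError as err:
            raise DegenerateSeriesError(f"feature {name}: {err}") from err

    m1, s1 = guarded(lambda: corr_summary(autocorr_function(R, K)), "acf(R)")
    m2, s2 = guarded(lambda: corr_summary(autocorr_function(P, K)), "acf(P)")
    m3, s3 = guarded(lambda: corr_summary(crosscorr_function(R, P, K)), "ccf(R,P)")
    m4, s4 = guarded(lambda: corr_summary(crosscorr_function(P, E, K)), "ccf(P,E)")
    m5, s5 = _decay_summary(R)
    return FeatureVector(
        values=(m1, s1, m2, s2, m3, s3, m4, s4, m5, s5),
        model_label=model_label,
        replicate=replicate,
    )


def feature_table(R, P, E, n_vectors: int, window: int | None = None,
                  K: int = 300, rng: np.random.Generator | None = None,
                  model_label: str = "") -> np.ndarray:
    """n_vectors feature vectors from random (replicate, window) draws.

    Each vector is computed on a contiguous window of one replicate row;
    with ``window=None`` the full row is used and rows are cycled.  This is
    how a feature sample larger than the replicate count is obtained from
    an F-replicate data set.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    E = np.atleast_2d(np.asarray(E, dtype=float))
    F, L = R.shape
    if window is None:
        window = L
    if window < K + 2 or window > L:
        raise ValueError("window must satisfy K+2 <= window <= L")
    rng = np.random.default_rng() if rng is None else rng
    out = np.empty((n_vectors, len(FEATURE_NAMES)), dtype=float)
    for k in range(n_vectors):
        i = int(rng.integers(0, F)) if window < L or F > 1 else 0
        start = int(rng.integers(0, L - window + 1))
        sl = slice(start, start + window)
        out[k] = feature_vector(R[i, sl], P[i, sl], E[i, sl], K=K,
                                model_label=model_label, replicate=i).as_array()
    return out


def z_transform(vectors) -> np.ndarray:
    """Column-wise z-transform: each feature gets mean 0, sample variance 1."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D collection with >= 2 vectors")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i)
               for i in np.flatnonzero(sd == 0)]
        raise DegenerateSeriesError(f"constant feature column(s): {bad}")
    return (X - X.mean(axis=0)) / sd
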