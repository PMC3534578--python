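"""Pause-presence detection by resampled windowed-mean t-tests.

Whether a gene carries a long sequence-dependent pause site is decided by
comparing the mean molecule numbers of two data sets (models M and M').
A *mean profile* is built by repeatedly drawing a replicate row i and a
window start uniformly at random and averaging the dL+1 consecutive
samples; two S-long profiles are compared by Welch's two-sample t-test of
their means.  Repeating the whole procedure N times yields a population
of N p-values whose median (and the fraction below alpha) summarises
detectability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timeseries import TimeSeriesMatrix

__all__ = ["MeanProfile", "PValueSet", "sample_mean_profile", "compare_models"]


@dataclass(frozen=True)
class MeanProfile:
    """S window means drawn from one replicate matrix."""

    means: np.ndarray
    window: int  # dL: the window covers dL+1 consecutive samples
    source_kind: str = ""


@dataclass(frozen=True)
class PValueSet:
    """Population of p-values from repeated profile comparisons."""

    p_values: np.ndarray
    window: int
    profile_size: int
    n_repeats: int
    n_indeterminate: int = 0
    labels: tuple[str, str] = ("M", "M'")

    def median(self) -> float:
        return float(np.median(self.p_values))

    def fraction_below(self, alpha: float = 0.05) -> float:
        return float(np.mean(self.p_values < alpha))


def sample_mean_profile(matrix: TimeSeriesMatrix, dL: int, S: int,
                        rng: np.random.Generator) -> MeanProfile:
    """Draw S windowed means; each window covers dL+1 consecutive samples.

    For each of the S draws a replicate row i ~ unif{1..F} and a window
    start Ls ~ unif{1..L-dL} are sampled independently (both endpoints
    inclusive), and the mean of the dL+1 values starting at Ls is taken.
    """
    F, L = matrix.F, matrix.L
    if dL >= L:
        raise ValueError("window length dL must be < L")
    if S < 1:
        raise ValueError("S must be >= 1")
    cums = np.cumsum(matrix.values.astype(np.float64), axis=1)
    rows = rng.integers(0, F, size=S)
    starts = rng.integers(0, L - dL, size=S)  # 0-based start in [0, L-dL-1]
    ends = starts + dL  # inclusive; window has dL+1 samples
    totals = cums[rows, ends] - np.where(starts > 0, cums[rows, starts - 1], 0.0)
    return MeanProfile(means=totals / (dL + 1), window=dL, source_kind=matrix.kind)


def compare_models(matrix_M: TimeSeriesMatrix, matrix_Mp: TimeSeriesMatrix,
                   dL: int, S: int, N: int,
                   rng: np.random.Generator) -> PValueSet:
    """N independent Welch t-tests between fresh S-long mean profiles.

    Degenerate draws (both profiles with zero variance) are excluded from
    the p-value set and counted, never coerced to a numeric p.
    """
    if matrix_M.kind != matrix_Mp.kind:
        raise ValueError("matrices must hold the same kind of counts")
    if matrix_M.sample_interval != matrix_Mp.sample_interval:
        raise ValueError("matrices must share the sampling interval")
    if S < 2:
        raise ValueError("S must be >= 2 for a t-test")
    p_values = []
    n_indet = 0
    for _ in range(N):
        a = sample_mean_profile(matrix_M, dL, S, rng).means
        b = sample_mean_profile(matrix_Mp, dL, S, rng).means
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            n_indet += 1
            continue
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        if np.isnan(p):
            n_indet += 1
            continue
        p_values.append(float(p))
    return PValueSet(p_values=np.asarray(p_values), window=dL, profile_size=S,
                     n_repeats=N, n_indeterminate=n_indet,
                     labels=(matrix_M.model_label or "M",
                             matrix_Mp.model_label or "M'"))
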