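"""Replicate count matrices (RNA / protein / cumulative protein).

Simulation replicates are assembled into F x L integer matrices sampled at
a fixed interval (1 s by default): ``R`` holds RNA numbers, ``P`` protein
numbers and ``E`` the cumulative number of proteins produced.  Utilities
remove the non-stationary burn-in and test weak stationarity of the
retained span with a two-sample t-test on ensemble means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "TimeSeriesMatrix",
    "assemble",
    "cumulative_from_events",
    "truncate_burnin",
    "stationarity_check",
    "StationarityResult",
    "write_matrix",
    "read_matrix",
]

KINDS = ("rna", "protein", "cumulative-protein")


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """F x L matrix of non-negative integer counts sampled at 1 Hz-like grid."""

    kind: str
    values: np.ndarray
    sample_interval: float = 1.0
    burnin_offset: float = 0.0
    model_label: str = ""
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 2:
            raise ValueError("values must be F x L with F >= 1, L >= 2")
        if np.any(v < 0):
            raise ValueError("counts must be non-negative")
        if self.kind == "cumulative-protein" and np.any(np.diff(v, axis=1) < 0):
            raise ValueError("cumulative-protein rows must be non-decreasing")
        object.__setattr__(self, "values", v)

    @property
    def F(self) -> int:
        return self.values.shape[0]

    @property
    def L(self) -> int:
        return self.values.shape[1]


def cumulative_from_events(event_times, grid) -> np.ndarray:
    """Cumulative number of production events at each grid time.

    ``event_times`` are the times at which single productions occurred
    (repeats allowed); the result counts events with time <= grid point.
    """
    t = np.sort(np.asarray(event_times, dtype=float))
    grid = np.asarray(grid, dtype=float)
    return np.searchsorted(t, grid, side="right").astype(np.int64)


def assemble(rows, kind: str, sample_interval: float = 1.0,
             model_label: str = "", seeds=()) -> TimeSeriesMatrix:
    """Stack equal-length replicate series into a matrix.

    For ``kind="cumulative-protein"`` each element of ``rows`` may instead
    be a tuple ``(event_times, grid)``, in which case the cumulative count
    is computed from the production events (the running total of events,
    not the instantaneous protein number).
    """
    mats = []
    for row in rows:
        if kind == "cumulative-protein" and isinstance(row, tuple):
            event_times, grid = row
            mats.append(cumulative_from_events(event_times, grid))
        else:
            mats.append(np.asarray(row, dtype=np.int64))
    lengths = {m.shape[-1] for m in mats}
    if len(lengths) != 1:
        raise ValueError(f"ragged replicate lengths: {sorted(lengths)}")
    return TimeSeriesMatrix(kind=kind, values=np.vstack(mats),
                            sample_interval=sample_interval,
                            model_label=model_label, seeds=tuple(seeds))


def truncate_burnin(matrix: TimeSeriesMatrix, t0: float = 50_000.0) -> TimeSeriesMatrix:
    """Drop all columns before time ``t0`` (seconds) and record the offset."""
    duration = matrix.L * matrix.sample_interval
    if t0 >= duration:
        raise ValueError("burn-in must be shorter than the series")
    n_drop = int(round(t0 / matrix.sample_interval))
    if n_drop == 0:
        return matrix
    return replace(matrix, values=matrix.values[:, n_drop:],
                   burnin_offset=matrix.burnin_offset + t0)


@dataclass(frozen=True)
class StationarityResult:
    status: str  # "pass" | "fail" | "indeterminate"
    p_value: float | None
    alpha: float

    def __bool__(self) -> bool:
        return self.status == "pass"


def stationarity_check(matrix: TimeSeriesMatrix, n_sample: int = 10,
                       alpha: float = 0.05,
                       rng: np.random.Generator | None = None) -> StationarityResult:
    """Weak-stationarity check by a two-sample t-test on ensemble means.

    ``n_sample`` column means (ensemble means over replicates) are drawn
    uniformly at random from the first third of the span and ``n_sample``
    from the last third; Welch's two-sided t-test compares the two groups.
    Passes when p > alpha.  Zero-variance windows are reported as
    indeterminate rather than a pass.
    """
    if matrix.L < 2 * n_sample:
        raise ValueError("matrix too short for the requested sample size")
    rng = np.random.default_rng() if rng is None else rng
    third = matrix.L // 3
    if third < n_sample:
        raise ValueError("each third must contain at least n_sample columns")
    col_means = matrix.values.mean(axis=0)
    early = col_means[rng.choice(third, size=n_sample, replace=False)]
    late = col_means[matrix.L - third + rng.choice(third, size=n_sample, replace=False)]
    if np.ptp(early) == 0 and np.ptp(late) == 0:
        if early[0] == late[0]:
            return StationarityResult("indeterminate", None, alpha)
        return StationarityResult("fail", 0.0, alpha)
    p = float(stats.ttest_ind(early, late, equal_var=False).pvalue)
    return StationarityResult("pass" if p > alpha else "fail", p, alpha)


# ---------------------------------------------------------------------------
# TSV + JSON sidecar persistence

def write_matrix(matrix: TimeSeriesMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (one row per replicate) plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, matrix.values, fmt="%d", delimiter="\t")
    meta = {
        "kind": matrix.kind,
        "sample_interval": matrix.sample_interval,
        "burnin_offset": matrix.burnin_offset,
        "model_label": matrix.model_label,
        "seeds": list(matrix.seeds),
        "shape": list(matrix.values.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(path: str | Path) -> TimeSeriesMatrix:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=np.int64))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return TimeSeriesMatrix(kind=meta["kind"], values=values,
                            sample_interval=meta["sample_interval"],
                            burnin_offset=meta["burnin_offset"],
                            model_label=meta["model_label"],
                            seeds=tuple(meta["seeds"]))
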