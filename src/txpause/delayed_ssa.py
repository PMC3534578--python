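"""Generic delayed stochastic simulation algorithm (delayed SSA).

An exact Gillespie direct-method simulator extended with a *waiting list*:
any reaction product may be released after an arbitrarily distributed time
delay instead of instantaneously.  A delayed event ``A -> B + C(tau)``
produces ``B`` at the firing time ``t`` and places ``C`` on the waiting
list until ``t + tau``, with ``tau`` drawn afresh from the product's delay
distribution at every firing.

The engine is deliberately simple and general: species are named integer
counters, propensities are mass action (with optional guard predicates for
occupancy-dependent channels), and the waiting list is a priority queue
keyed on release time.  Ties between a reaction firing and a waiting-list
release at the same instant are resolved release-first (fixed convention).
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DelayDistribution",
    "DelayedReaction",
    "SimState",
    "Trajectory",
    "ConfigurationError",
    "draw_delay",
    "step",
    "simulate",
    "EXHAUSTED",
]

#: Sentinel returned by :func:`step` when no reaction can fire and the
#: waiting list is empty.  Not an exception: callers decide how to proceed.
EXHAUSTED = "exhausted"


class ConfigurationError(ValueError):
    """Invalid model configuration (bad rate, delay parameter, ...)."""


@dataclass(frozen=True)
class DelayDistribution:
    """Distribution of the release delay of one reaction product (seconds).

    Supported kinds:

    ``"point"``
        Degenerate distribution; ``params = (value,)``.  A point mass at 0
        behaves as an instantaneous product.
    ``"exponential"``
        ``params = (mean,)``.
    ``"normal"``
        Normal truncated at zero by rejection resampling,
        ``params = (mean, sd)``.  Clipping is deliberately avoided: it
        would put an atom at 0 and bias the mean.  For the delays used in
        the gene-expression model (e.g. N(40, 4^2), N(420, 100^2)) the
        rejection probability is negligible.
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind == "point":
            (value,) = self.params
            if value < 0:
                raise ConfigurationError("point-mass delay must be >= 0")
        elif self.kind == "exponential":
            (mean,) = self.params
            if mean < 0:
                raise ConfigurationError("exponential delay mean must be >= 0")
        elif self.kind == "normal":
            mean, sd = self.params
            if sd < 0 or not math.isfinite(mean):
                raise ConfigurationError("normal delay needs finite mean, sd >= 0")
        else:
            raise ConfigurationError(f"unknown delay kind {self.kind!r}")

    @staticmethod
    def point(value: float) -> "DelayDistribution":
        return DelayDistribution("point", (float(value),))

    @staticmethod
    def exponential(mean: float) -> "DelayDistribution":
        return DelayDistribution("exponential", (float(mean),))

    @staticmethod
    def normal(mean: float, sd: float) -> "DelayDistribution":
        return DelayDistribution("normal", (float(mean), float(sd)))


def draw_delay(dist: DelayDistribution, rng: np.random.Generator) -> float:
    """Draw one non-negative delay (seconds) from ``dist``."""
    if dist.kind == "point":
        return dist.params[0]
    if dist.kind == "exponential":
        mean = dist.params[0]
        return float(rng.exponential(mean)) if mean > 0 else 0.0
    # truncated normal by rejection
    mean, sd = dist.params
    if sd == 0:
        if mean < 0:
            raise ConfigurationError("degenerate normal delay with negative mean")
        return mean
    while True:
        x = float(rng.normal(mean, sd))
        if x >= 0.0:
            return x


@dataclass
class DelayedReaction:
    """One reaction channel with optional delayed products and a guard.

    Propensity is mass action: ``rate * prod_s falling_factorial(count_s,
    stoich_s)``, zero whenever a reactant is missing or the guard fails.
    ``on_fire`` may return an iterable of new :class:`DelayedReaction`
    objects to add to the running system (used to instantiate per-molecule
    reaction sets, e.g. translation machinery for a newly made transcript).
    """

    identifier: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    delayed_products: Sequence[tuple[str, int, DelayDistribution]] = ()
    rate: float = 0.0
    guard: Callable[["SimState"], bool] | None = None
    on_fire: Callable[["SimState"], Iterable["DelayedReaction"] | None] | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError(f"negative rate for reaction {self.identifier}")

    def propensity(self, state: "SimState") -> float:
        a = self.rate
        if a == 0.0:
            return 0.0
        for species, stoich in self.reactants.items():
            n = state.counts.get(species, 0)
            if n < stoich:
                return 0.0
            for k in range(stoich):  # falling factorial
                a *= n - k
        if a > 0.0 and self.guard is not None and not self.guard(state):
            return 0.0
        return a


@dataclass
class SimState:
    """Species counts, waiting list and clock of one delayed-SSA run."""

    counts: dict[str, int]
    time: float = 0.0
    waiting: list[tuple[float, int, str, int]] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    _tiebreak: itertools.count = field(default_factory=itertools.count, repr=False)

    def enqueue(self, release_time: float, species: str, count: int = 1) -> None:
        if release_time < self.time:
            raise ValueError("waiting-list release time precedes current time")
        heapq.heappush(self.waiting, (release_time, next(self._tiebreak), species, count))

    def copy(self) -> "SimState":
        new = SimState(dict(self.counts), self.time, list(self.waiting), self.rng)
        return new


def _fire(state: SimState, reaction: DelayedReaction,
          live: list[DelayedReaction]) -> None:
    for species, stoich in reaction.reactants.items():
        state.counts[species] = state.counts.get(species, 0) - stoich
        if state.counts[species] < 0:  # pragma: no cover - guarded by propensity
            raise RuntimeError(f"negative count for {species}")
    for species, stoich in reaction.products.items():
        state.counts[species] = state.counts.get(species, 0) + stoich
    for species, count, dist in reaction.delayed_products:
        tau = draw_delay(dist, state.rng)
        if tau == 0.0:
            state.counts[species] = state.counts.get(species, 0) + count
        else:
            state.enqueue(state.time + tau, species, count)
    if reaction.on_fire is not None:
        new = reaction.on_fire(state)
        if new:
            live.extend(new)


def step(state: SimState, reactions: list[DelayedReaction]) -> str | None:
    """Advance the system by one event (reaction firing or delayed release).

    The next reaction time is sampled from the total propensity; if the
    earliest waiting-list release precedes it (ties: release-first), that
    release is performed instead.  Returns :data:`EXHAUSTED` (and leaves
    the state untouched) when nothing can ever happen again.
    """
    props = [r.propensity(state) for r in reactions]
    total = float(sum(props))
    t_release = state.waiting[0][0] if state.waiting else math.inf

    if total <= 0.0:
        if math.isinf(t_release):
            return EXHAUSTED
        t_next = math.inf
    else:
        t_next = state.time + state.rng.exponential(1.0 / total)

    if t_release <= t_next:
        release_time, _, species, count = heapq.heappop(state.waiting)
        state.time = release_time
        state.counts[species] = state.counts.get(species, 0) + count
        return None

    state.time = t_next
    u = state.rng.random() * total
    acc = 0.0
    chosen = len(props) - 1
    for i, a in enumerate(props):
        acc += a
        if u < acc:
            chosen = i
            break
    _fire(state, reactions[chosen], reactions)
    return None


@dataclass
class Trajectory:
    """Sampled trajectory: integer counts of each observable on a time grid."""

    times: np.ndarray
    counts: np.ndarray  # shape (len(times), len(observables))
    observables: tuple[str, ...]
    seed: int | None = None

    def column(self, name: str) -> np.ndarray:
        return self.counts[:, self.observables.index(name)]

    def write_tsv(self, path, metadata: Mapping | None = None) -> None:
        """Write the trajectory as TSV (time + one column per observable)
        plus a JSON sidecar with the seed and a config hash."""
        import hashlib
        import json
        from pathlib import Path

        path = Path(path)
        header = "time\t" + "\t".join(self.observables)
        body = np.column_stack([self.times, self.counts])
        fmt = ["%.10g"] + ["%d"] * len(self.observables)
        np.savetxt(path, body, fmt=fmt, delimiter="\t", header=header,
                   comments="")
        meta = dict(metadata or {})
        meta.setdefault("seed", self.seed)
        meta["config_hash"] = hashlib.sha256(
            json.dumps(meta, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1, default=str))


def simulate(
    reactions: Sequence[DelayedReaction],
    initial_counts: Mapping[str, int],
    t_end: float,
    sample_interval: float = 1.0,
    observables: Sequence[str] | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Run a delayed-SSA simulation and sample it on a regular grid.

    Samples are taken at t = 0, d, 2d, ..., each reflecting the state
    immediately *after* all events with event-time <= sample time
    (right-continuous convention, fixed).  Identical seed and
    configuration give a bit-identical trajectory.
    """
    if t_end <= 0 or sample_interval <= 0:
        raise ConfigurationError("t_end and sample_interval must be > 0")
    live = list(reactions)
    state = SimState(dict(initial_counts), rng=np.random.default_rng(seed))
    if observables is None:
        observables = sorted(initial_counts)
    observables = tuple(observables)

    n_samples = int(math.floor(t_end / sample_interval + 1e-9)) + 1
    times = np.arange(n_samples) * sample_interval
    out = np.zeros((n_samples, len(observables)), dtype=np.int64)
    filled = 0  # number of grid points already recorded

    def snapshot() -> list[int]:
        return [state.counts.get(s, 0) for s in observables]

    while filled < n_samples:
        pre = snapshot()
        t_before = state.time
        status = step(state, live)
        t_event = state.time if status is None else math.inf
        # grid points strictly before the event keep the pre-event state;
        # a grid point equal to the event time takes the post-event state,
        # which it receives on a later pass.
        while filled < n_samples and times[filled] < t_event - 1e-12:
            out[filled] = pre
            filled += 1
        if status == EXHAUSTED:
            while filled < n_samples:
                out[filled] = pre
                filled += 1
            break
        if t_event > t_end and filled < n_samples:
            # event beyond the horizon: remaining samples keep pre-event state
            while filled < n_samples:
                out[filled] = pre
                filled += 1
            break
        del t_before
    return Trajectory(times=times, counts=out, observables=observables, seed=seed)
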