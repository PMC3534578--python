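"""Experiment orchestration: replicate runs, matrices, fixtures.

`run_experiment` simulates F replicates of one model, assembles the RNA /
protein / cumulative-protein matrices, removes the burn-in and optionally
writes everything as TSV + JSON metadata.  Replicates regenerate the
codon sequence by default (instances of a model differ in their codon
sequences); per-replicate seeds are derived from the experiment seed with
numpy's seed-spawning so every output is reproducible from the config.

`make_fixture` builds small deterministic data sets exercising every
downstream operation; they are used by the test-suite and the examples.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import engine
from .expression_model import (GeneTemplate, ModelParameters, PauseSite,
                               make_gene_template, make_model)
from .timeseries import TimeSeriesMatrix, assemble, truncate_burnin, write_matrix

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "make_fixture",
           "FIXTURE_PRESETS"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulation experiment."""

    model_label: str = "A"
    gene_length: int = 1000
    t_end: float = 1_000_000.0
    n_replicates: int = 10
    sample_interval: float = 1.0
    burnin: float = 50_000.0
    seed: int = 0
    count_nascent: bool = True
    fixed_codon_sequence: bool = False
    pause_sites: tuple[tuple[int, float, float], ...] | None = None
    param_overrides: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.sample_interval <= 0:
            raise ValueError("durations must be > 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.burnin >= self.t_end:
            raise ValueError("burn-in must be shorter than the run")


@dataclass
class ExperimentResult:
    R: TimeSeriesMatrix
    P: TimeSeriesMatrix
    E: TimeSeriesMatrix
    config: RunConfig
    replicate_seeds: tuple[int, ...]
    wall_time_s: float


def _resolve_model(config: RunConfig, rng: np.random.Generator
                   ) -> tuple[GeneTemplate, ModelParameters]:
    params = ModelParameters(**config.param_overrides)
    if config.pause_sites is not None:
        sites = tuple(PauseSite(p, e, d) for p, e, d in config.pause_sites)
        template = make_gene_template(config.gene_length, sites, rng=rng)
    else:
        template, params = make_model(config.model_label, config.gene_length,
                                      rng=rng, params=params)
    return template, params


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Simulate, assemble and (optionally) persist one experiment."""
    t0 = time.time()
    root = np.random.default_rng(config.seed)
    rep_seeds = tuple(int(s) for s in
                      root.integers(0, 2**31 - 1, size=config.n_replicates))
    template0, params = _resolve_model(config, np.random.default_rng(config.seed))
    rna_rows, p_rows, e_rows = [], [], []
    for r, s in enumerate(rep_seeds):
        if config.fixed_codon_sequence or r == 0:
            template = template0
        else:
            template, _ = _resolve_model(config, np.random.default_rng(s))
        res = engine.simulate_expression(template, params, config.t_end,
                                         config.sample_interval, seed=s,
                                         count_nascent=config.count_nascent)
        rna_rows.append(res.rna)
        p_rows.append(res.protein)
        e_rows.append(res.protein_cum)
    label = config.model_label
    R = assemble(rna_rows, "rna", config.sample_interval, label, rep_seeds)
    P = assemble(p_rows, "protein", config.sample_interval, label, rep_seeds)
    E = assemble(e_rows, "cumulative-protein", config.sample_interval, label,
                 rep_seeds)
    if config.burnin > 0:
        R = truncate_burnin(R, config.burnin)
        P = truncate_burnin(P, config.burnin)
        E = truncate_burnin(E, config.burnin)
    result = ExperimentResult(R=R, P=P, E=E, config=config,
                              replicate_seeds=rep_seeds,
                              wall_time_s=time.time() - t0)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(R, out / f"{label}_R.tsv")
        write_matrix(P, out / f"{label}_P.tsv")
        write_matrix(E, out / f"{label}_E.tsv")
        meta = asdict(config) | {"replicate_seeds": list(rep_seeds),
                                 "wall_time_s": result.wall_time_s}
        (out / f"{label}_experiment.json").write_text(json.dumps(meta, indent=1))
    return result


#: Reduced-scale presets used by tests and examples.  "tiny" presets use a
#: 200-nt gene and short runs so they complete in seconds.
FIXTURE_PRESETS = {
    "tiny": dict(gene_length=200, t_end=10_000.0, burnin=3_000.0,
                 n_replicates=2, labels=("A",)),
    "tiny-AB": dict(gene_length=200, t_end=10_000.0, burnin=3_000.0,
                    n_replicates=2, labels=("A", "B")),
    "small-AB": dict(gene_length=1000, t_end=30_000.0, burnin=5_000.0,
                     n_replicates=2, labels=("A", "B")),
}


def make_fixture(preset: str, seed: int = 0) -> dict[str, ExperimentResult]:
    """Deterministic reduced-scale data sets keyed by model label."""
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(FIXTURE_PRESETS)}")
    spec = FIXTURE_PRESETS[preset]
    out = {}
    for k, label in enumerate(spec["labels"]):
        config = RunConfig(model_label=label, gene_length=spec["gene_length"],
                           t_end=spec["t_end"], burnin=spec["burnin"],
                           n_replicates=spec["n_replicates"],
                           seed=seed * 1009 + 17 * k + 1)
        out[label] = run_experiment(config)
    return out
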