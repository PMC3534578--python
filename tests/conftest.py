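"""Shared fixtures: reduced-scale simulated data sets.

All simulation fixtures are session-scoped and deterministic; the heavy
ones are shared between the unit tests and the acceptance tests so each
data set is simulated exactly once per session.  Problem sizes are
reduced relative to the full study (10 replicates of 10^6 s per model):
the reduced runs use the same kinetics, shorter horizons and fewer
replicates, with burn-in scaled to the slowest relaxation time
(protein lifetime ~345 s, folding delay ~420 s).
"""

from __future__ import annotations

import numpy as np
import pytest

from txpause.features import feature_table
from txpause.workflow import RunConfig, make_fixture, run_experiment

REDUCED_T_END = 30_000.0
REDUCED_BURNIN = 5_000.0


@pytest.fixture(scope="session")
def tiny_ab():
    """Two-model (A, B) fixture on a 200-nt gene, 5,000 s runs."""
    return make_fixture("tiny-AB", seed=1)


@pytest.fixture(scope="session")
def null_pair():
    """Two independent model-A data sets (for null-calibration checks).

    Long enough (2 x 55,000 stationary samples each) that the randomly
    drawn windows rarely overlap, so profile entries are effectively
    independent and the t-test operates under its nominal assumptions.
    """
    a1 = run_experiment(RunConfig(model_label="A", t_end=60_000.0,
                                  burnin=REDUCED_BURNIN, n_replicates=2,
                                  seed=101))
    a2 = run_experiment(RunConfig(model_label="A", t_end=60_000.0,
                                  burnin=REDUCED_BURNIN, n_replicates=2,
                                  seed=202))
    return a1, a2


@pytest.fixture(scope="session")
def six_model_data():
    """Reduced-scale replicate data for all six models A-F.

    4 replicates of 60,000 s per model (vs 10 x 10^6 s at full scale):
    long enough for 40,000-sample feature windows, which keep the
    feature noise below the between-model signal.
    """
    out = {}
    for k, label in enumerate("ABCDEF"):
        out[label] = run_experiment(
            RunConfig(model_label=label, t_end=60_000.0,
                      burnin=REDUCED_BURNIN, n_replicates=4,
                      seed=1000 + 7 * k))
    return out


@pytest.fixture(scope="session")
def six_model_features(six_model_data):
    """50 feature vectors per model from (replicate, window) draws."""
    tables = {}
    for k, (label, res) in enumerate(six_model_data.items()):
        rng = np.random.default_rng(42 + k)
        tables[label] = feature_table(res.R.values, res.P.values,
                                      res.E.values, n_vectors=50,
                                      window=40_000, rng=rng,
                                      model_label=label)
    return tables
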