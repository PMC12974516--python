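"""Shared fixtures: small synthetic datasets and one fitted GP decomposition.

Heavy objects are session-scoped so the whole suite pays for each expensive
fit exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import lineagegrowth as lg


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset: 10 lineages x 10 cells, 1-min sampling."""
    cfg = lg.SyntheticConfig(seed=11)
    return lg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def segmented_default(default_dataset):
    lset, truth = default_dataset
    segged = [lg.segment_cycles(ln.trace) for ln in lset]
    return segged, truth


@pytest.fixture(scope="session")
def gp_case():
    """One simulated lineage with trend + OU noise, segmented and GP-decomposed."""
    sim = lg.simulate_lineage(
        lg.OUParams(0.2, 1e-5), lambda0=0.068, trend=lg.cosine_bump(0.028),
        n_cells=6, dt=1.0 / 30.0, seed=4)
    lineage = lg.segment_cycles(sim.trace)
    inputs = lg.build_inputs(lineage, mitosis_window=0.5)
    decomp = lg.fit_decomposition(
        inputs, config=lg.FitConfig(n_exact=1200, n_opt=500, n_restarts=2,
                                    maxiter=50), seed=0)
    return sim, lineage, inputs, decomp


def truth_on_inputs(sim, lineage, inputs):
    """Ground-truth lambda_flucs / lambda_trend at the GP input grid points."""
    tr = sim.truth
    off = lineage.full_records[0].birth_time
    idx = np.clip(np.searchsorted(tr.times, inputs.t + off), 0, tr.times.size - 1)
    ok = np.abs(tr.times[idx] - (inputs.t + off)) < 1e-9
    return ok, tr.lambda_flucs[idx[ok]], tr.lambda_trend[idx[ok]]
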