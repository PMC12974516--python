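"""Fit the OU null model by variance matching and predict growth variability.

The two-parameter model (relaxation gamma, diffusion D) is fitted to the
fluctuation series by matching var(A_t), A_t the integrated fluctuation; the
fitted model then predicts the within-lineage SD of the cycle-averaged growth
rate, closing the loop of the analysis.
"""

import numpy as np

import lineagegrowth as lg
from lineagegrowth.ou_model import _truth_flucseries, fit_variance_matching

gamma_true, D_true = 0.2, 1e-5
sim = lg.simulate_lineage(lg.OUParams(gamma_true, D_true), lambda0=0.068,
                          fixed_tau=10.2, n_cells=25, dt=1 / 30, seed=5)
series = _truth_flucseries(sim, mitosis_window=0.5)

fit = fit_variance_matching(series)
print(f"fitted gamma: {fit.params.gamma:.3f} 1/h (true {gamma_true})")
print(f"fitted D:     {fit.params.diffusion:.2e} 1/h^3 (true {D_true:.2e})")

taus = sim.truth.taus
pred = lg.predict_cv(fit.params, taus, dt=1 / 30, lambda0=0.068,
                     n_reps=300, seed=6)
obs = sim.truth.lambda_bars.std(ddof=1)
print(f"predicted within-lineage SD(lambda_bar): "
      f"{pred.sd_lambda_bar:.5f} +/- {pred.sem_sd:.5f} 1/h")
print(f"observed in this lineage:                {obs:.5f} 1/h")
print("Agreement means continuous OU noise alone accounts for the "
      "cell-to-cell variability; division-specific noise is not needed.")
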