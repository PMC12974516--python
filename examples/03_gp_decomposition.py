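"""Decompose one lineage's log-mass signal into drift, age trend and fluctuations.

Fits the additive GP (linear drift + shared cell-age trend + integrated-OU
fluctuations + white noise) and prints the recovered growth-rate components.
"""

import numpy as np

import lineagegrowth as lg

sim = lg.simulate_lineage(
    lg.OUParams(gamma=0.2, diffusion=1e-5), lambda0=0.068,
    trend=lg.cosine_bump(0.028), n_cells=8, dt=1 / 30, seed=3)
lineage = lg.segment_cycles(sim.trace)
inputs = lg.build_inputs(lineage, mitosis_window=0.5)
decomp = lg.fit_decomposition(inputs, config=lg.FitConfig(
    n_exact=1500, n_opt=550, n_restarts=2, maxiter=50), seed=0)

print(f"log marginal likelihood: {decomp.log_marginal_likelihood:.1f}")
print(f"lineage drift lambda0:   {decomp.lambda0_mean:.4f} 1/h (true 0.068)")
order = np.argsort(inputs.u)
lt = decomp.lambda_trend[order]
print(f"age-trend peak:          u = {inputs.u[order][np.argmax(lt)]:.2f} "
      f"(true 0.50), birth-to-peak rise {lt.max() - lt[0]:.4f} 1/h (true 0.028)")
print(f"fitted OU relaxation:    {1 / decomp.spec.gamma:.1f} h (true 5.0 h)")
diag = lg.residual_diagnostics(decomp)
print(f"residual lag-1 R^2:      {diag['lag1_r2']:.4f} "
      "(white residuals mean measurement noise was absorbed, not leaked "
      "into the fluctuation component)")
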