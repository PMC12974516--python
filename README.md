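# lineagegrowth

Tools for analysing long-term single-cell **mass growth** in ancestral
lineages — chains of cells followed through many divisions with one daughter
retained at each division, as measured by a suspended microchannel resonator
(SMR) at ~1-minute, ~0.1% precision.  The scientific question the package
addresses: when genetically identical cells grow at different rates, is that
variability produced by cell-size control, by events at cell division, or by
continuous noise in the growth machinery itself?

The package is aimed at researchers working with single-cell growth traces
(mass, volume, or any positive size signal sampled densely in time) who want
to decompose growth into interpretable components and test noise models
against lineage data.

## The models

**Growth decomposition.**  With per-cell log masses pasted into one
continuous signal `f(t)` (mitoses excised), an additive Gaussian process
separates

    f(t) = lambda0 * t + f_trend(u) + f_flucs(t) + eps(t)

where `lambda0` is the lineage's mean exponential rate, `f_trend` is a smooth
function of the *relative cell age* `u = (t - t_birth)/tau` shared by every
cell of the lineage, `f_flucs` carries the continuous fluctuations, and
`eps` is white measurement noise.  Derivatives of the posterior give the
instantaneous growth-rate components `lambda_trend` and `lambda_flucs`.

**Null model of growth noise.**  The isolated fluctuations are modelled as an
Ornstein-Uhlenbeck process, optionally kicked at divisions:

    d lambda_flucs = -gamma * lambda_flucs dt + sqrt(2 D) dW,
    lambda_flucs -> lambda_flucs + Normal(0, sigma_z)   at division.

`sigma_z = 0` is division-blind continuous noise; `D = 0` puts all noise at
divisions.  The two limits separate observably: the variance of the
time-averaged growth rate `var(lambda_bar_t)` falls as `t^-1` (continuous)
versus `t^-2` (kicks), and the MSD ratio
`MSD_between / (MSD_within + MSD_between)` of `lambda_flucs` sits near 0.5
for division-blind noise but approaches 1 for kicks.

**Size control.**  The autoregressive parameter `a` (`Mf = 2(1-a) M0 +
2a E[M0] + xi`; 0 = timer, 0.5 = adder, 1 = sizer), its covariance twin
`alpha = -cov(ln M0, lambda_bar * tau)/var(ln M0)`, and the growth-rate share
`alpha_lambda = -E[tau] * cov(ln M0, lambda_bar)/var(ln M0)` quantify whether
and how cells correct size deviations.

A fully parameterized synthetic-data generator (adder division control,
age-dependent growth trend, OU fluctuations, near-symmetric division,
measurement noise) provides ground truth for every stage.

## Worked example

```python
import lineagegrowth as lg

sim = lg.simulate_lineage(
    lg.OUParams(gamma=0.2, diffusion=1e-5), lambda0=0.068,
    trend=lg.cosine_bump(0.028), n_cells=8, dt=1/30, seed=3)
lineage = lg.segment_cycles(sim.trace)
inputs  = lg.build_inputs(lineage, mitosis_window=0.5)
decomp  = lg.fit_decomposition(inputs, seed=0)
```

Running `examples/03_gp_decomposition.py` (exactly the above plus printing)
gives

```
log marginal likelihood: 2769.7
lineage drift lambda0:   0.0659 1/h (true 0.068)
age-trend peak:          u = 0.48 (true 0.50), birth-to-peak rise 0.0315 1/h (true 0.028)
fitted OU relaxation:    7.3 h (true 5.0 h)
residual lag-1 R^2:      0.0004
```

The decomposition recovers the lineage rate, places the growth-rate peak
mid-cycle with the right amplitude, finds a relaxation time of the right
scale, and leaves white residuals — the measurement noise went into `eps`,
not into the fluctuation component.  The other scripts in `examples/` walk
through segmentation and variability summaries (`01`), size-control
estimation (`02`), fluctuation statistics and the MSD ratio (`04`), and OU
inference with closed-loop prediction of cell-to-cell variability (`05`).

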