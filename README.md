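# chanclust

Tools for studying how voltage-gated ion channels organize into clusters in
the surface membrane of arterial smooth muscle cells, and how that
organization shapes channel activity.

In arterial myocytes, KV2.1 (a delayed-rectifier K⁺ channel) assembles into
micro-clusters that can coalesce into large *macro-clusters*, and the extent
of macro-clustering tunes the clustering and cooperative gating of L-type
CaV1.2 Ca²⁺ channels in a sex-specific way. `chanclust` implements the
computational core of this kind of study as a reusable, tested pipeline:

* **Stochastic self-assembly simulation** (`chanclust.assembly`): a lattice
  model in which channels nucleate with probability *p_n* per empty site,
  clusters grow with probability *p_g* per adjacent empty site, and channels
  are removed with probability *p_r* per occupied site, per synchronous
  step. At steady state the cluster-size distribution develops the
  exponential tail characteristic of stochastic self-assembly, and the three
  rates can be fit to an observed size distribution by grid search.
* **Cluster segmentation and size analysis** (`chanclust.clusters`):
  fixed-threshold 3D spot segmentation (26-connected components, >2-voxel
  and 100 nm lateral / 150 nm axial minima), per-cell metrics including the
  percent of surface membrane occupied, single-exponential fits
  `N(V) = A·exp(−V/τ)` to cluster-size histograms, macro/micro
  classification at the mean − 2·SD volume threshold, single-molecule
  localization + 20 nm/px rendering, confocal-equivalent Gaussian blur, and
  proximity-ligation puncta quantification.
* **Sparklet analysis** (`chanclust.sparklets`): idealization of quantal
  Ca²⁺ sparklet traces (100 Hz) into integer open-channel levels, site
  activity nPs = Σₖ k·Tₖ/T with a 0.2 low/high cutoff, and
  maximum-likelihood estimation of the coupling coefficient κ ∈ [0, 1] under
  a coupled binary Markov chain, P = (1−κ)·P_indep + κ·P_sync, where κ = 0
  means independent gating and κ = 1 means all channels open and close
  together.
* **Current-density prediction** (`chanclust.ephys`): linear scaling of a
  100%-functional reference IV by the fraction f of conductive channels,
  blocker-subtraction of current families, and IV extraction from
  voltage-step recordings.
* **Synthetic data** (`chanclust.synthetic`): generators for every input the
  pipeline consumes — exponential cluster populations on a membrane shell,
  rendered confocal-like stacks (0.13 μm z-step), coupled-gating traces with
  known κ, and blink movies — all seeded and reproducible, so every analysis
  stage can be validated against known ground truth.

## Worked example

```python
from chanclust import clusters, ephys, sparklets, synthetic

# Macro/micro threshold from a measured mean ± SD cluster volume
thr = clusters.macro_threshold(0.12, 0.03)
print(thr.threshold)                  # 0.06  (μm³)

# Current density expected if only 1% of KV2.1 channels conduct
pred = ephys.scale_current(ephys.MALE_REFERENCE_IV, 0.01)
print(pred.reported[0])               # 70.1  (pA/pF at +50 mV)

# Recover a known coupling coefficient from a simulated sparklet site
spec = synthetic.SparkletSimSpec(n_channels=3, kappa_true=0.4,
                                 open_prob=0.1, duration=20.0, seed=1)
trace, truth = synthetic.gen_sparklet_trace(spec)
est = sparklets.estimate_kappa(truth, n_channels=3)
print(round(est.kappa, 3))            # 0.384
```

The first number is the macro-cluster lower volume limit (mean minus two
standard deviations); the second is the whole-cell KV2.1 current density
predicted when 1% of channels are functional; the third is the
maximum-likelihood κ recovered from a single 2000-frame trace generated at
κ = 0.4 (averaging over seeds brings the mean estimate to within ±0.1 of
the truth).

A command-line interface wraps the same functionality:

```sh
chanclust predict-current --sex female --fraction 0.1
chanclust make-fixtures --seed 1 --out fixtures/
chanclust simulate-assembly --params params.json --seed 1 --out dist.csv
chanclust run-pipeline --config pipeline.json --seed 1
```

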