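# bilat

Analysis pipeline for a classic question in motor neuroscience: how does a
single hemisphere of primary motor cortex (M1) represent mechanical loads
applied to the *contralateral* arm — the one it drives — versus the
*ipsilateral* arm?  Given trial-structured spike recordings from a postural
perturbation task (eight shoulder/elbow torque combinations per arm), the
package quantifies per-neuron load tuning, response onset timing,
restructuring of pairwise correlations between the two contexts, and the
demonstration that the two contexts occupy near-orthogonal population
subspaces — so a downstream readout can extract one arm's signal with almost
no interference from the other's.

It is written for systems/computational neuroscientists who want these
analyses as tested, seedable library functions, and it ships a synthetic
session generator with controllable ground truth (subspace alignment,
tuning bimodality, gain ratio, onset lag) so every stage has a recovery
test without any external data.

## The statistics at the core

With `C, I ∈ R^(N×CT)` the soft-normalized, mean-subtracted
neuron × (condition·time) activity matrices of the two contexts and
`Cov_c, Cov_i` their covariances:

- **Alignment index** of the top-k contralateral principal components
  `P_c` against the ipsilateral activity:

      A(c on i) = Tr(P_cᵀ Cov_i P_c) / Σ_{j=1..k} λ_j(Cov_i),

  normalized by the most variance any k orthonormal directions could
  capture, so A ∈ [0, 1] with 0 = orthogonal subspaces, 1 = aligned (and
  symmetrically for A(i on c)).  Significance comes from a
  variance-weighted random-subspace null.

- **Joint orthogonalization** finds jointly orthonormal per-context bases
  `[Q_c | Q_i]` on a Stiefel manifold maximizing

      ½ [ Tr(Q_cᵀ Cov_c Q_c)/Σ_{j≤d} λ_j(Cov_c)
        + Tr(Q_iᵀ Cov_i Q_i)/Σ_{j≤d} λ_j(Cov_i) ],

  then measures the **relative projection difference**
  `100·‖P_ref − P_other‖_F/‖P_ref‖_F` between the two contexts inside one
  context's dimensions (≈100% means the other context contributes nothing
  there).

- **Per-neuron tuning**: planar fits `rate = β₀ + β_s τ_s + β_e τ_e` in
  joint-torque space (preferred angle `atan2(β_e, β_s)`, magnitude in
  Hz/Nm), three-way load-sensitivity ANOVA, Rayleigh unimodal/bimodal
  statistics with a uniform bootstrap, Wilcoxon magnitude contrasts.

- **Onsets**: causal post-spike kernel smoothing (1 ms rise, 20 ms fall),
  3-SD/20-ms threshold rule on best-load averages, cross-fitted population
  onset traces.

- **Correlation change**: median |r_contra − r_ipsi| over all neuron pairs
  against a trial-split bootstrap null.

## Worked example

`examples/subspace_alignment.py` simulates a 90-neuron session whose two
context subspaces have ground-truth alignment 0.15, then runs the subspace
chain:

```
ground-truth alignment: 0.15
alignment index: contra-on-ipsi 0.21, ipsi-on-contra 0.18 (mean 0.20)
random-subspace null: 0.77 +- 0.10; p = 0.000 (smaller index = more orthogonal)
3 orthogonal contra dims: 69% of contra variance, 3% of ipsi variance
3 orthogonal ipsi dims:   47% of ipsi variance, 2% of contra variance
relative difference in contra dims: 92% (95% CI [91, 94])
relative difference in ipsi dims: 79% (95% CI [78, 85])
```

Reading: the measured alignment index (0.20) sits far below what random
subspaces of this data would produce (0.77), confirming the configured
near-orthogonality; three orthogonalized dimensions per context capture
most of their own context's variance and almost none of the other's; and
inside either context's dimensions the other context's projection differs
by nearly 100% — i.e. it is essentially absent.  The other examples cover
simulation (`simulate_and_inspect.py`), tuning (`tuning_analysis.py` —
bimodal preferred-load distributions, 2:1 contra:ipsi magnitude ratio),
onset timing (`onset_timing.py` — the ~10 ms ipsilateral lag), correlation
restructuring (`correlation_change.py`) and the end-to-end orchestrator
(`full_pipeline.py`).

## Command line

```sh
bilat simulate --seed 1 --out session_dir          # trials.csv, spikes.csv, groundtruth.json
bilat run --seed 1 --out results_dir               # full pipeline -> report.json
bilat run --config cfg.yaml --seed 1 --out out_dir # with SimConfig/pipeline overrides
```

`report.json` nests every statistic with its null summary and the seeds
used; a rerun with the same config and seed reproduces it bit-for-bit.

## Layout

```
src/bilat/
  core.py          session types, canonical load set, CSV/JSON I/O
  simulate.py      ground-truth synthetic sessions
  preprocess.py    kernels, rate series, epoch means, context matrices
  tuning.py        ANOVA, planar fits, circular statistics
  onsets.py        threshold onset detection, population onsets
  correlations.py  pairwise correlation change + trial-split null
  subspace.py      PCA, alignment index + null, Stiefel orthogonalization
  peripheral.py    EMG/kinematics filtering and epoch statistics
  pipeline.py      orchestration, seeding, report writing
  cli.py           `bilat` command-line entry point
docs/methods.md    full methods note (models, estimators, conventions)
examples/          one narrative script per capability
```
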