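# Methods

This note documents the models, numerical choices, and open design
decisions behind `netswitch`, and what the synthetic-data validation does
and does not establish about real data.

## Signal conditioning and windowed connectivity

A scan is a node × time matrix at a fixed sampling interval (default TR =
2 s). Conditioning follows the conventional resting-state order:

1. **Nuisance residualization** (`regress_nuisance`): ordinary least
   squares of each node series on an intercept plus arbitrary regressor
   columns (e.g. the global mean signal; the pipeline's `gsr: true` default
   regresses the global mean, since global-signal regression is the common
   recommendation for dynamic-FC motion control). The operation is an exact
   projection — applying it twice changes nothing beyond rounding.
2. **Band-pass** (`bandpass`): zero-phase frequency-domain masking keeping
   0.01–0.10 Hz inclusive. Masking was chosen over an IIR/FIR design
   because it is exactly bounded (out-of-band gain identically zero), has
   no edge transient, and makes the synthetic generator's spectra exactly
   reproducible. The trade-off — implicit circularity of the DFT — is
   immaterial for correlation estimates on 50-volume windows.
3. **Windowing**: rectangular (untapered) windows of `width` 50 volumes,
   `step` 1, after trimming `trim_initial` 10 volumes. Window count is
   ⌊(T − trim − width)/step⌋ + 1; indexing is 0-based half-open throughout,
   including file outputs.
4. **Connectivity**: Pearson correlation per window, clipped to
   |r| ≤ 1 − 1e−7 and Fisher z-transformed (`atanh`). Clipping bounds the
   edge weights, which the modularity stage requires to be finite. The
   diagonal is zero (no self-edges). Negative entries are zeroed by
   `zero_negative` *after* the transform; since atanh preserves sign this
   is equivalent to zeroing before, and the order is fixed only for
   reproducibility. A zero-variance node segment raises an error naming the
   node and window rather than propagating NaNs.

**Motion bookkeeping.** Mean framewise displacement uses the displacement
formulation: FD_t = Σ|Δtranslation| + 50 mm × Σ|Δrotation in radians|,
averaged over frames 2..T. Rotations are assumed stored in degrees (the
common tool convention); a `rotation_unit` flag accepts radians. The
gross-motion screen fails a scan when any axis exceeds 2 mm translation or
2° rotation (strict inequality), reporting the offending axis.

## Multilayer modularity and its optimization

The quality function is the standard single-aspect temporal multilayer
modularity: per-layer Newman–Girvan null with layer-specific strengths
(k_is k_js / 2m_s), resolution γ, and ordinal coupling ω between a node and
itself in adjacent layers; 2μ sums all intra-layer strengths and both
directions of every coupling. A layer with zero total weight contributes no
null term (its null is defined as 0). For a single layer the function
reduces exactly to weighted Newman–Girvan modularity — the test suite pins
this against an independent graph-library implementation, and pins the
general case against a brute-force sum over all (i, j, s, r).

Defaults γ = 1, ω = 1 with ordinal (adjacent-layer) coupling follow the
documented conventions of the generalized Louvain literature; both are
exposed because no universal choice exists. All-to-all coupling is not
implemented (ordinal is the standard choice for temporal stacks), nor are
multi-aspect networks or signed extensions.

Optimization is a generalized Louvain on the supra-modularity matrix
(node–layer vertices; dense null-adjusted blocks per layer, ω on the ±n
off-diagonals; memory proportional to L·n² plus couplings, ~40 MB at
160 × 191):

- **Local moves**: vertices are visited in a seed-shuffled order; a vertex
  joins the candidate community with the largest gain, ties broken by the
  first-encountered candidate in a seed-shuffled candidate order, moves
  accepted only above a tolerance (default 1e−10 in Q units). Departing to
  a fresh singleton community is always a candidate, so the "no improving
  move" stopping condition is meaningful. Q never decreases across
  accepted moves.
- **Aggregation**: communities collapse into super-vertices and the sweep
  repeats until no move helps or no merge occurs.
- **Labels** are globally meaningful across layers (a label is the same
  community in every layer), which is what makes consecutive-window label
  comparisons well defined; they are canonicalized 0..K−1 by first
  appearance scanning nodes then layers, so outputs are comparable across
  runs.
- The returned Q is recomputed from the final labels with the quality
  function, guaranteeing self-consistency.

Runs are deterministic given a seed. Because different seeds land in
different local optima, the protocol runs `n_repetitions` independent
restarts (default 100, matching common practice) with seeds
`seed + k`, and averages the derived *rates* — not the partitions — across
repetitions. Repetition seeds are pre-assigned, so results do not depend on
execution order. On instances small enough to enumerate (≤ 8 node–layer
vertices) the restarted optimizer attains the exhaustive-search maximum;
at realistic sizes only local optimality is guaranteed, which is exactly
why the repetition protocol exists.

## Switching rates

f_i = n_i / N with n_i the number of consecutive-layer label changes and
N = layers − 1. No layer-to-layer label matching is applied — the
multilayer labels are already globally aligned, and introducing a matching
step would double-count the coupling's job. Subnetwork and global rates are
unweighted means over member nodes ("averaging the nodes", not
size-weighted). Rates are invariant under any global relabeling;
lengthening the stack with a duplicate final layer leaves n_i fixed and
strictly lowers every positive f_i. Averaging across repetitions happens at
the node-rate level; by linearity, aggregate-then-average equals
average-then-aggregate, and the test suite asserts this to 1e−12.

## Synthetic cohorts: what is emulated

The generator exists because scans of this kind are rarely shareable; it
plants structure that the full pipeline must recover.

**Scans.** A planted design assigns each node a module at every volume: a
schedule of partition intervals plus sparse per-node switch events, applied
in order of event volume (an event overrides the node's label from its
volume onward, until a later event). The signal model is

    x_i(t) = √c · u_m(i,t)(t) + σ · η_i(t)

with u_m and η_i independent unit-variance Gaussian series, band-limited by
frequency-domain masking to the analysis band, c = `within_module_corr`
(default 0.6, a realistic within-system BOLD coupling) and σ = `noise_sd`
(default √(1−c)). Expected same-module correlation is c/(c+σ²) — exactly c
at the default σ, approaching 1 as σ → 0, monotone decreasing in σ — and
cross-module correlation is 0. The loading model was chosen precisely so
these expectations are closed-form testable. Motion traces are
small-amplitude random walks (step SD 0.01 mm / 0.01°); mean FD is computed
from them. No hemodynamics, no spatial structure, no scanner artifacts.

**Ground truth.** `planted_switch_rate` summarizes each sliding window by
the node's majority scheduled label (ties to the earliest-appearing label)
and counts majority changes between consecutive windows — the quantity the
pipeline should recover. Random event placement keeps each node's events at
least one window width apart and in increasing volume order, so each event
flips exactly one window majority; when the requested event count exceeds
what spacing allows, surplus events may coincide and the realized rate
falls short of the nominal one (the tests therefore compare against the
design's own `planted_switch_rate`, never against event counts).

**Cohorts.** Two arms ("dependent", "control"; sizes configurable,
e.g. 24/26) with two scans each. Per subject, a latent z draws the number
of pre-scan events (heterogeneity), and clinical scores are tied to z by a
Gaussian copula with configurable correlation (default: dependence-severity
score at ρ = 0.5, so fixture cohorts qualitatively resemble a
dependence–rate association; it is a free parameter, not a calibrated
one). Covariate and score distributions default to two-arm values typical
of a small dependence study (ages ≈ 23.5/24.5 ± 3.9/1.5 years, education
15.1 ± 1.7 vs 16.0 years, depression/anxiety scores elevated in the
dependent arm). Post-exposure designs append `round(effect · n_nodes · N)`
extra events, raising the mean planted rate by ≈ `effect`. Outcome values
attached to the cohort are exact planted rates plus Gaussian noise
(`outcome_noise_sd`, default 0.02) standing in for finite-repetition
measurement error; a full pipeline run replaces them with measured rates.
Per-subject randomness uses fixed spawn keys from the master seed, so
enlarging a cohort never perturbs existing subjects, and scans are realized
lazily (cohort-level Monte-Carlo never pays scan-synthesis cost).

**What passing tests show — and don't.** Planted recovery demonstrates the
pipeline is a consistent estimator of its own generative model's switching
structure under strong modularity (two 10-node modules at c = 0.8). Real
data have weaker, overlapping, drifting modules, hemodynamic confounds and
sampling variability, so recovery there will be noisier; nothing here
validates the neuroscientific interpretation of switching rates.

## Statistics

All p-values are two-sided; significance convention α = 0.05.

- **ANCOVA** group effect: F from nested OLS fits (full vs without the
  binary group factor). With a single two-level factor the sums-of-squares
  type is immaterial. Rank deficiency is reported with the offending
  column's name.
- **Paired t** on post − pre differences; per-group post-hocs mirror the
  whole-sample test.
- **Two-sample t from summaries** (means/SDs/sizes) in pooled and Welch
  variants — published demographics tables are internally consistent with
  pooled for some rows and Welch for others, so the variant is an explicit
  argument rather than a hidden variance pre-test.
- **Spearman** with mid-rank ties; p by the t-approximation (adequate at
  n ≈ 24), with an exact permutation option for n ≤ 10.
- **Partial Pearson**: residualize both variables on the covariates,
  correlate residuals, df = n − k − 2. A variable the covariates explain to
  rounding noise gets r = 0 by convention rather than a correlation of
  noise.
- **FDR**: Benjamini–Hochberg step-up, applied within each test family
  across the level's outcomes (6 subnetworks or all nodes); the single
  global outcome is tested uncorrected. Whether the original protocol also
  corrected the group-difference family is not specifiable from public
  information; this implementation corrects every family at local levels.
- The study battery is exactly the reported design — no group × time
  interaction model, no mixed-effects extension.

Type-I calibration (10,000-replicate simulated nulls) holds the paired t,
ANCOVA F, and Spearman tests within 0.05 ± 0.01 at α = 0.05.

## Problem sizes in tests and the acceptance script

Full-scale geometry (160 nodes × 191 windows, ~30,560 supra-vertices) is
exercised once per run for the structural checks; a single optimization
takes seconds. Recovery and power checks run at 20 nodes × 240 volumes with
5 optimization restarts and 100 cohort replicates of 25 + 25 subjects;
calibration uses 10,000 replicates. These sizes were chosen so the whole
validation completes in about a minute while keeping every Monte-Carlo
margin several standard errors wide; the repetition default for real
analyses remains 100.

## Known limitations

- Greedy Louvain guarantees only local optima at realistic sizes; quality
  across seeds varies slightly (hence the repetition protocol).
- The optimizer's sweep is pure Python/NumPy per vertex; very large
  parcellations (≫ 500 nodes) would benefit from a compiled inner loop.
- The generator's modules are disjoint and piecewise constant; no overlap,
  no gradual transitions, no amplitude nonstationarity.
- Windowed correlation itself biases dynamics estimates (autocorrelation,
  window-length trade-offs); the package implements the standard method, it
  does not correct its estimator properties.
- Consensus partitions, recruitment/integration matrices, promiscuity and
  other dynamic metrics are out of scope.
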