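# Methods

This note documents the models, default parameters and numerical choices
behind `botanitox`, in the order the pipeline runs them, and states what the
synthetic-data generator does and does not emulate.

## Synthetic study model

The generator (`botanitox.synthetic_data`) emulates a plate-based botanical
screen with known ground truth. True responses follow a Hill model

    r(c) = top · c^h / (EC50^h + c^h),

with `top` the maximal % response (signed per the endpoint's direction of
effect; exactly 0 for inactive truths), `EC50` in µg/mL and Hill coefficient
`h` dimensionless. Raw well signal is

    raw = V_DMSO_mean + (V_pos_mean − V_DMSO_mean) · (r(c) + ε) / 100 + g(col),

with `ε ~ N(0, noise_sd²)` additive Gaussian noise on the % response scale
and `g` an optional linear column gradient. Putting the noise on the
response scale makes the configured noise threshold directly interpretable
in response units; control-well raw SDs default to the same noise level
expressed in signal units, so the threshold derived from DMSO wells matches
the substance-well noise.

Study structure and defaults:

* 19 botanical groups × (4 lots + 1 constituent) ≈ 95 substances,
  20 endpoints with randomly assigned direction labels, 3 replicate runs —
  the scale of the screening design this package targets.
* Titration: 15 points at third-log steps from a 500 µg/mL top
  concentration. Screens of this kind only fix the 10 mg/mL DMSO stock; the
  in-well range is a free design parameter and these defaults give a
  ~4.7-decade range typical of designed titrations.
* Plate layout: one 384-well plate holds 16 substances (rows A–P), columns
  1–2 declared empty, the titration in columns 3–17, 16 DMSO wells in
  column 23 and 16 positive-control wells in column 24. Larger substance
  sets split across plates; more than 20 dilution points is rejected rather
  than silently truncated.
* Activity: each group×endpoint is truly active with probability 0.3; active
  truths draw `|top| ~ U(40, 120)` %, `h ~ U(0.8, 2.5)`, and
  `log10 EC50 ~ U(log10 c_min + 2, log10 c_max − 0.7)`. The EC50 floor of
  two decades above the lowest tested concentration keeps the two lowest
  points on the baseline plateau — the assumption behind per-curve baseline
  rescaling; titrations in practice are designed the same way.
* Lots within a group share the group truth jittered by a log-normal factor
  (SD 0.15); constituents get 1.25× the efficacy (capped at 150%) and a
  4-fold lower EC50 than their parent extract, emulating the elevated
  activity of purported active constituents.

Not emulated: chemistry-based constituent concentrations, spectral
autofluorescence (exclusion is a boolean flag), PAINS-style promiscuity
beyond counter-screen activity, non-additive plate artifacts, and
inter-plate titration layouts. Passing tests therefore demonstrate that the
analysis recovers Hill-shaped truths under additive Gaussian noise — not
that it is robust to every artifact of real screening data.

## Normalization

`% Response = (V_substance − V_DMSO)/(V_pos − V_DMSO) × 100` with median
control values per plate×endpoint×run. Plates whose two control medians
coincide are rejected as degenerate. Baseline rescaling subtracts the median
response of the two lowest tested concentrations, per curve (whether the
original analysis rescaled per curve or per plate is not stated; per-curve
is implemented and is idempotent by construction). Decrease-direction
endpoints are sign-flipped at normalization time so one code path handles
both directions; signs are restored on reported wAUC and Emax.

Pattern correction is a pluggable hook with default `none`. The
`median_polish` method estimates additive column and row effects from the
plate's baseline wells (DMSO wells plus each substance's lowest tested
concentration), removes them from all non-empty wells, and restores the
plate-wide DMSO median exactly. Column effects are estimated first and
interpolated/extrapolated linearly across columns without baseline coverage:
baseline wells within a column share that column's effect directly, whereas
a row mixes several columns' effects (row-first estimation absorbs half of a
pure column gradient). The method removes a linear gradient exactly on a
noise-free plate and is a deliberately simple stand-in: well-level QC and
non-additive corrections are out of scope.

## Noise threshold and curve filter

Per endpoint, `T = max(k · SD(DMSO responses), data_floor, min_threshold)`
with `k = 3`, the data floor the 95th percentile of |response| at the two
lowest concentrations pooled over all substance curves, and
`min_threshold = 1%` guarding zero-variance (e.g. noise-free synthetic)
input. How the SD term and the substance-data term should be combined is a
design decision of this package; max-with-floor keeps the threshold from
collapsing on quiet plates while letting systematically noisy baselines
raise it. At least 8 DMSO values are required.

The filter applies, in order: (1) isolated single-point spikes (interior
points differing from both neighbors by more than `T` with opposite-signed
jumps) replaced by the neighbor mean, iterated to a fixpoint; (2) responses
with |r| < `T` set to 0; (3) a weak monotone envelope in the direction of
effect — a drop below the running maximum smaller than `T` is clipped to the
running maximum, a larger drop zeroes the remainder of the curve (loss of
response treated as noise beyond recovery). After filtering, every nonzero
response is ≥ `T`, which makes *significant*, |wAUC| > 0 and "POD present"
equivalent by construction.

Known property: the filter is not globally monotone in `T`. Raising the
threshold can switch a post-peak drop from tail-zeroing to clipping (and can
preserve a spike that a lower threshold removed), which can increase |wAUC|
or lower the POD for pathological curves. On monotone-rise curves — the
shape the Hill model produces — raising `T` provably shrinks |wAUC| and
raises the POD, and the property tests check exactly that.

## Activity parameters

* wAUC: `trapz(response, log10 c) / (100 · (log10 c_max − log10 c_min))`,
  sign restored per endpoint direction. A constant full-scale response gives
  1; an all-zero filtered curve gives exactly 0.
* POD: first crossing of `T`, interpolated linearly in log10 concentration
  on the *pre-zeroing* magnitudes so a curve crossing between grid points
  gets a between-grid POD; a first point already above threshold returns the
  lowest tested concentration; ties resolve to the lowest qualifying
  concentration.
* Emax: the filtered response of maximal magnitude (first occurrence on
  ties). EC50: first concentration reaching Emax/2, interpolated the same
  way. Both absent for all-zero curves. No nonlinear Hill fit is performed;
  benchmark-dose modelling and POD confidence intervals are out of scope.

## Calls

Majority rule: active iff `n_significant / n_runs > 0.5`. Runs that fail to
yield a usable curve (fewer than 4 points) count as non-significant rather
than shrinking `n_runs` — conservative toward inactivity. Medians over an
even number of present values are midpoint means. The counter-screen
interference window and the AroER dilution-factor cutoff are not fixed by
the screening literature this package follows; both default to 3-fold
(≈ one half-log dilution step) and are configuration keys. Relabelling to
inconclusive drops the potency medians (potency is only assigned to
actives). Real-time cytotoxicity integration sums the per-timepoint median
wAUCs and takes the most potent POD across active time points; the summary
EC50/Emax are taken from the time point achieving that POD (only the wAUC
and POD summaries are prescribed; carrying the companion values of the most
potent time point keeps the summary self-consistent).

## Profiling

POD analytics use the primary endpoints only; correlation and embedding use
all assay readouts including counter screens. Inactive/inconclusive POD
cells are imputed at 1000 µg/mL (log10 = 3), wAUC cells at 0. Clustering is
average-linkage (UPGMA) on Euclidean distances with lexicographic pre-sorting
for deterministic tie-breaks. Spearman correlation uses average ranks for
ties; the undefined-correlation assignments are: both profiles all-zero → 1,
any other constant profile involved → 0, negative correlations → 0.
Between-group correlation curves compare each member with the most active
lot of every other group (most active = largest active-endpoint count, ties
by larger |Σ wAUC|, then lexicographic id); curves are emitted per comparator
group and pooled, since either presentation may be wanted.

Enrichment uses the classical one-way F statistic
`(SSB/df₁)/(SSW/df₂)` computed directly (an independent reference ANOVA is
used in tests, never as the implementation). Zero within-group variance with
distinct group means yields +inf, flagged `infinite` and ranked first;
all-identical values yield 0/0, flagged `degenerate` and ranked last.

Ranking Z-scores are computed per endpoint across the substance set with
population SD (ddof 0); by default only the active cells of an endpoint
enter the Z-scoring (`zscore_on="active"`, matching a sum over active
responses), with `"all"` as a configuration switch. Endpoints with fewer
than two qualifying cells or zero variance contribute 0. Ranks are dense
and shared on ties.

The 2-D embedding is t-SNE on a precomputed Euclidean distance matrix of
wAUC profiles, random initialization, no PCA preselection, default
perplexity 30 and 5000 iterations, exact gradient at desk scale (< 2000
substances) — deterministic for a fixed seed. Perplexity is reduced with a
warning when the substance set is too small for the requested value.

## Problem sizes used in the test suite

Tests run on simulated studies sized to exercise every code path while
keeping the suite fast: parameter-recovery checks use 200 substances ×
4 endpoints × 3 runs at 5% response noise (800 truth pairs); the
false-positive-rate property uses 200 truly inactive substances at a fixed
threshold; determinism checks run the full pipeline (including the
embedding at 500 iterations) twice on a 32-substance study. The defaults of
`SimulationDesign` remain the full-size study (~95 substances ×
20 endpoints).

## Known limitations

* The curve filter and wAUC weighting are this package's concrete,
  documented procedure — simple, deterministic and zero-iff-inactive — not a
  reimplementation of any proprietary filtering code; likewise the pattern
  correction hook.
* POD/EC50 are grid-interpolated, so their resolution is bounded by the
  dilution spacing; very shallow curves whose analytic POD falls below the
  tested range are reported at the lowest tested concentration.
* The correlation assignment rules make the correlation surface a similarity
  in [0, 1], not a proper correlation matrix; it is not guaranteed positive
  semidefinite.
* The false-positive rate of the activity calls is self-stabilizing because
  the noise threshold is derived from the data; at a *fixed* threshold the
  rate grows with the noise level, which is what the corresponding property
  test measures.
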