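# botanitox

Quantitative high-throughput screening (qHTS) analysis for botanical and
dietary supplement test panels.

Botanical supplements are complex mixtures: the same ingredient is sold as
different lots, extracts, oils and purported active constituents, and none of
them can be characterized by a single chemical structure. One practical way
to assess them is a *bioactivity fingerprint*: screen every test article
across a panel of cell-based concentration–response assays (nuclear receptor
activity, stress response, genotoxicity, viability, ...) and compare the
resulting activity profiles. `botanitox` implements the full analysis chain
for such a screen, from raw 384-well plate reads to profile-level analytics,
together with a synthetic-study generator with known ground truth so every
stage can be validated without access to screening data.

## The analysis

**Normalization.** Each raw well read is expressed relative to its own
plate's controls,

    % Response = (V_substance − V_DMSO) / (V_pos − V_DMSO) × 100,

where `V_DMSO` and `V_pos` are the medians of the solvent-only and
positive-control wells. Curves are baseline-rescaled to 0% (median of the
two lowest tested concentrations) and decrease-direction endpoints are
sign-flipped internally so all downstream math treats effect as a positive
response. An optional pattern-correction hook removes smooth additive plate
gradients.

**Noise filtering and activity parameters.** A per-endpoint noise threshold
`T = max(k·SD(DMSO), data floor)` (k = 3 by default) drives a three-stage
curve filter: isolated spikes are replaced by their neighbor mean,
sub-threshold responses are zeroed, and a weak monotone envelope is enforced
in the direction of effect. Each filtered curve is summarized by four
activity parameters:

* **wAUC** — trapezoidal integral of response over log10 concentration,
  normalized by `100·(log10 c_max − log10 c_min)`; exactly 0 when nothing
  exceeds the threshold, and |wAUC| > 0 defines a *significant* curve;
* **POD** — the concentration at which the response first equals `T`
  (log-linear interpolation);
* **EC50 / Emax** — concentration of half-maximal response and the maximal
  response.

**Activity calls.** A substance is *active* on an endpoint when more than
half of its replicate curves are significant (two of three runs); potency
parameters are medians over the runs that assigned them, and inactive calls
carry none. Active calls whose paired counter screen fires within a 3-fold
POD window become *inconclusive*; real-time cytotoxicity time points are
integrated (summed wAUC, most potent POD); aromatase-inhibition calls that
ER antagonism can explain are flagged.

**Profiling.** Calls become two matrices — log10 POD over the primary
endpoints with inactive/inconclusive cells imputed at 1000 µg/mL, and wAUC
over all readouts (counter screens included, 0 for non-active cells). On top
of these: UPGMA clustering (Euclidean distance, average linkage) for heatmap
ordering; pairwise Spearman correlation with the screening rules (negative
values → 0; both profiles all-zero → 1; exactly one all-zero → 0); one-way
ANOVA F-values ranking endpoints by how strongly they separate botanical
groups, and the F-ratio (fine/coarse grouping) isolating extract-versus-
constituent differences; three substance rankings (number of active
endpoints, most potent POD, sum of Z-scored wAUC over active responses); and
a seeded 2-D t-SNE on precomputed Euclidean distances between wAUC profiles.

## Worked example

```python
import botanitox as bt

design = bt.SimulationDesign(
    n_groups=6, lots_per_group=3, constituents_per_group=1,
    n_endpoints=6, runs=3, noise_sd=5.0, seed=42,
)
config = bt.StudyConfig(perplexity=7, tsne_iterations=1000, seed=42)
results = bt.run_pipeline(design, config)

print(results["calls"].label.value_counts().to_dict())
top = results["rankings"].sort_values("rank_sum_z_wauc").head(5)
print(top[["substance_id", "n_active", "min_pod", "sum_z_wauc"]].round(3))
```

prints

```
{'inactive': 97, 'active': 47}
substance_id  n_active  min_pod  sum_z_wauc
grp04-const1         3    0.079       5.592
  grp04-lot1         3    0.362       3.008
  grp04-lot2         3    0.776       1.908
grp01-const1         2    0.137       1.835
grp06-const1         2    0.252       1.824
```

47 of the 144 substance×endpoint pairs are called active. The most active
substance is a *constituent* (`grp04-const1`): the generator gives purported
active constituents larger true efficacy and lower EC50 than their parent
extracts, and the ranking recovers that — it is active in 3 of 6 endpoints
with a most potent POD of 0.079 µg/mL, ahead of the lots of its own group.
`min_pod` is in µg/mL; `sum_z_wauc` is the dimensionless sum of per-endpoint
Z-scored wAUC values over the substance's active endpoints.

The same stages are available from the shell:

```sh
botanitox simulate --config design.yaml --out plates.csv \
    --truth truth.csv --substances substances.csv --endpoints endpoints.csv
botanitox normalize --in plates.csv --endpoints endpoints.csv \
    --out curves.csv --dmso-out dmso.csv
botanitox fit --in curves.csv --dmso dmso.csv --endpoints endpoints.csv --out metrics.csv
botanitox call --in metrics.csv --endpoints endpoints.csv --n-runs 3 --out calls.csv
botanitox profile --calls calls.csv --substances substances.csv \
    --endpoints endpoints.csv --out-dir results/
```

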