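# enmrange

Ensemble ecological niche modelling (ENM/SDM) with dispersal-constrained
range-change projection and landscape fragmentation metrics.

`enmrange` is aimed at spatial ecologists who want to ask, reproducibly:
*given presence/absence records for a species and gridded environmental
layers, where is suitable habitat now, where will it be under warming, and
how much of the gained habitat is actually reachable for a poorly
dispersing species?*  The motivating use case is guilds of flightless,
range-restricted specialists (e.g. alpine insects on a two-island
landmass), where absences for one species can be derived from survey
records of the others and where habitat gained on a disconnected island is
biologically out of reach.

## The method

For each species with presences **y** at covariates **X** (continuous
climate layers filtered for collinearity, plus static categorical layers):

1. **Collinearity filtering.** Variance inflation VIF_j = 1/(1 − R²_j) and
   iterative removal of the higher-VIF member of any variable pair with
   |r| > 0.85, until no pair exceeds the threshold.
2. **Candidate models.** Ten learners — GLM, GBM, GAM, CTA, ANN, SRE, FDA,
   MARS, RF, MAXENT — each fitted on 3 random 80/20 calibration/evaluation
   splits (30 candidates), with record weights giving presences and
   absences equal total weight (prevalence 0.5).
3. **Evaluation.** ROC = P(random presence outranks a random absence,
   ties ½) and TSS = max over cutoffs of (sensitivity + specificity − 1);
   the TSS-maximising cutoff is stored per model.  Variable importance is
   1 − Pearson r between predictions on intact and column-shuffled data,
   averaged over 3 permutations.
4. **Ensemble.** Members are candidates with ROC > 0.9 (fallback > 0.8);
   the weighted-mean ensemble EMwm = Σ wᵢ pᵢ with wᵢ ∝ member ROC.
   Ensemble variable importance applies the member weights to the
   run-averaged importances of the full 30-model set, divides by the
   number of methods, and reports percentages summing to 100.
5. **Range change.** The consensus binary map marks a pixel suitable when
   > 50% of candidates exceed their own cutoff.  Comparing current vs
   scenario maps classifies pixels never/always/lost/gained; net change =
   gain% − loss% relative to the current range, where the *no-dispersal*
   mode counts a gained pixel only if its future habitat patch
   (8-connected) contains an always-occupied pixel.
6. **Fragmentation.** Patches are connected components of the binary map
   with geodesic pixel areas (spherical cells, ≈ 0.86 km² at the equator
   at 30 arc-seconds); patches < 0.1 km² are excluded.  Reported metrics:
   patch count, total and mean patch area, splitting index
   SPLIT = A²/Σaᵢ², and aggregation index AI = 100·g/g_max over rook
   adjacencies.

A synthetic-world generator (two islands split by a sea channel, a smooth
temperature gradient, Gaussian-random-field precipitation analogues, a
categorical soil layer, and logistic "true niches") makes the entire
pipeline testable end to end against closed-form truth.

## Worked example

```python
import enmrange as er

world = er.generate_world(er.WorldSpec(shape=(60, 60)), seed=7)
niches = er.default_niches(world, n_species=6, seed=7,
                           dominant_layer="temp_gradient")
occ = er.sample_occurrences(world, niches, n_sites=300, seed=8)
occ, report = er.filter_occurrences(occ, world.extent)
table = er.derive_absences(occ, "sp01", world)          # absences from the
X, y, _ = er.extract_covariates(world, table)           # other species
models, failures = er.fit_all(X, y, categorical=["soil"], seed=9)
ensemble = er.build_ensemble(models, X_test=X, y_test=y)

warm = er.apply_scenario(world, er.ScenarioSpec("rcp26", temperature_delta=1.0))
cutoffs = [m.cutoff for m in models]
cur = er.binarize_consensus(er.project_models(models, world), cutoffs, world.mask)
fut = er.binarize_consensus(er.project_models(models, warm), cutoffs, world.mask)
trans = er.classify_transitions(cur, fut)
```

Printing the intermediate results of this session gives:

```
records: 291 (122 presences)
candidate models: 30, failed: 0
ensemble: 25 members at ROC gate 0.9, ROC 0.987, TSS 0.858
importance (%): {'temp_gradient': 91.2, 'precip_field1': 4.8,
                 'precip_field2': 2.6, 'soil': 1.5}
transitions: {'never': 1841, 'always': 344, 'lost': 1055, 'gained': 0}
dispersal:    loss 75%  gain 0%  net -75%
no_dispersal: loss 75%  gain 0%  net -75%
current: patches 2  area 1399 km²  SPLIT 10.7   AI 97.5
rcp26:   patches 4  area  344 km²  SPLIT 165.4  AI 91.5
```

Reading this: 30 candidate models were fitted; 25 cleared the ROC > 0.9
gate; the ensemble correctly identifies the temperature gradient as the
dominant niche driver (91.2% of importance — the true niche was built
with a dominant temperature coefficient).  Under +1.0° of warming this
cold-adapted species loses 75% of its consensus range with nothing
gained, and the surviving habitat is markedly more fragmented: total area
falls 1399 → 344 km² while the splitting index rises 10.7 → 165.4 and the
aggregation index falls 97.5 → 91.5.

The same analysis for every species in a compilation, driven by a flat
YAML config, is one command:

```bash
enmrange run-all --seed 7 --out my_run     # synthetic world by default
enmrange report my_run
```

which writes per-species `evaluation.csv`, `ensemble.csv`,
`emwm_importance.csv`, `range_change.csv`, `fragmentation.csv`, and
suitability/binary/transition `.asc` grids, plus a `run_log.json` and a
`summary.csv` (top predictor and integer net-change percentages per
scenario × dispersal mode).

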