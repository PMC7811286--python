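# nichespread

Ecological niche modelling and invasion-spread simulation for
range-expansion risk assessment.

`nichespread` is for ecologists and invasion biologists who need to (a)
estimate a species' climatically suitable area from presence-only
occurrence records and gridded environmental predictors, and (b) ask how
far the species could spread across that area from known points of
introduction. The package implements the full workflow as a tested
library plus a thin command-line interface, and ships a seeded
virtual-species generator so that every stage can be exercised — and its
correctness checked against known ground truth — without any external
data.

## What it computes

**Suitability.** A Maxent-style presence–background model: a Gibbs
density over the background cells of the accessible area M,

    P(cell) = exp(λ·f(cell)) / Z,

with feature transforms f (linear, quadratic, product, threshold, hinge)
of range-rescaled predictors, and weights λ minimizing the
L1-regularized objective

    −mean_presence(λ·f) + log Σ_background exp(λ·f) + Σ_j β_j |λ_j|,

where β_j scales with the regularization multiplier *rm*. Output is the
raw normalized density or the cloglog index 1 − exp(−e^H · raw) ∈ [0, 1]
(H = entropy of the raw distribution).

**Model selection.** Candidates enumerate rm × feature-class set ×
predictor subset (4,560 configurations for 6 predictors with the default
grids; 880 for 4 principal components). Each candidate is scored on
random 50/50 occurrence splits by partial ROC (AUC-ratio statistic above
a sensitivity floor 1 − E, significance from a landscape-matched Monte
Carlo null), omission at E = 5%, and AICc; selection keeps significant,
low-omission candidates within ΔAICc ≤ 2.

**Risk screening and spread.** MOP (mobility-oriented parity) scores the
environmental similarity of each projection cell to the calibration
cloud and flags strict extrapolation (any variable outside its
calibration range); flagged cells are trimmed from binary maps. A
deterministic cellular automaton then spreads occupation from seed cells
across suitable cells within Moore radius d per step; a sweep over
connectivity radii {1, 2, 4, 8, 10, 12} × 10 threshold levels (3–10%)
yields the percentage of scenarios in which each cell is reached. A
presence–absence matrix on a coarse grid summarizes multi-species
richness.

See `docs/methods.md` for the model details, parameter defaults and
design choices.

## Worked example

Run the whole pipeline on a generated virtual species with a known
niche:

```python
import json
from scipy.stats import spearmanr
from nichespread import PipelineConfig, run_pipeline, make_virtual_species

species = make_virtual_species(seed=1)          # 60x60 grid, 3 variables, 200 records
config = PipelineConfig(rms=(0.5, 1, 2), class_sets=("lq", "lqp"),
                        n_boot=200, seed=1)
result = run_pipeline(species, config)

print(json.dumps(result.manifest["stages"], indent=1))
best = result.selected[0]
print(best.config.label(), best.proc_p, best.omission_rate)
rho = spearmanr(result.consensus_median.values.ravel(),
                species.true_suitability.values.ravel()).statistic
print("rank correlation with truth:", round(rho, 3))
```

This prints, among the per-stage counts: 200 records cleaned, 75 kept
after 50-km distance thinning, 3,600 background cells in M, 24
candidates evaluated over 5 splits (120 evaluations), 12 selected, 40
bootstrap replicates passing the independent-record test, and 60
dispersal scenarios. The best-AICc selected model is
`rm=0.5_fc=lqp_vars=env1+env2` (partial-ROC p ≈ 0.005, omission ≈
0.027) — the model correctly drops the nuisance variable `env3` — and
the consensus suitability ranks cells like the true niche (Spearman ρ ≈
0.93). The dispersal sweep reaches 2,438 of 3,600 cells in more than
half of the 60 scenarios.

The same stages are available as shell commands:

```bash
nichespread make-fixture --seed 1 --out-dir fixture/
nichespread clean fixture/occurrences.csv fixture/countries.geojson --out clean.csv
nichespread thin clean.csv --min-km 50 --seed 1 --out thinned.csv
nichespread run --seed 1 --out-dir run1/
```

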