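# crossfeed

Tools for studying the evolution of fitness-costly vitamin secretion in
an obligate cross-feeding microbial community: a riboflavin-auxotrophic
yeast that depends on vitamin-secreting lactic acid bacteria, which in
turn depend on amino acids the yeast releases. Serial co-culture of such
a community selects for bacteria that secrete *more* vitamin despite the
metabolic cost — the opposite of the cheater takeover naive theory
predicts — and this package implements the three computational pieces
used to understand and quantify that result:

* **`crossfeed.abm` / `crossfeed.experiment`** — an agent-based model of
  the community on a 32 x 32 patch grid under a serial-transfer protocol,
  and the replicated invasion experiment that asks when a single
  over-secreting mutant (1.5x, 2x, 3x wild-type secretion, at
  proportional energy cost) survives 25 transfers. Spatial structure is
  controlled by a mixing parameter in [0, 1]: at mixing 0 agents never
  move within a growth phase, at mixing 1 every agent is re-placed at
  random every tick.
* **`crossfeed.marge`** — expression-constrained flux balance fitting:
  given a stoichiometric model and enzyme log2 fold-changes (evolved vs
  parental, filtered at |log2FC| >= 0.5), predict paired flux
  distributions that best fit the abundance ratios while each condition
  stays within 3% of its optimal nutrient uptake and total enzymatic
  flux (a proteome proxy) is conserved. Ships a small riboflavin-branch
  network; reads SBML for user-supplied genome-scale models.
* **`crossfeed.phenomics`** — the phenotype formulas used to score
  evolved isolates: secretion fold-changes against a parental baseline,
  growth rates as the maximal sliding-window slope of log2(OD),
  generation counts log10(Af/Ai)/0.3, aggregation percentages, biofilm
  readouts, and the unpaired two-tailed t-test.
* **`crossfeed.synthetic`** — seeded generators (logistic growth curves,
  screening plates, flux-fit cases) that return their ground truth, so
  the whole pipeline runs and is tested without any external data.

## Worked example

```python
from crossfeed.abm import SimConfig
from crossfeed.experiment import run_replicates, summarize
from crossfeed.marge import estimate_specific_rate
from crossfeed.phenomics import fold_change

# Secretion fold-changes of two evolved isolates measured by LC-MS
# (titers in ng/ml against the parental mean of 42):
fold_change(134.0, 42.0)   # -> (3.190..., 1.674...)   "3.2-fold"
fold_change(426.0, 42.0)   # -> (10.14..., 3.342...)   "circa 10-fold"

# The parental specific riboflavin production rate from an end-point
# titer (42 ng/ml after 72 h at OD600 2, half the biomass producing):
estimate_specific_rate(42.0, 72.0, 2.0)   # -> 6.131e-06 mmol/(gCDW h)

# Invasion of a 2x-secreting mutant without mixing, 20 replicates
# (200 in the full experiment):
outs = run_replicates(SimConfig(mixing=0.0, mutant_secretion_fold=2.0),
                      n_replicates=20, base_seed=0)
cell = summarize(outs)
print(cell.invasion_percent, cell.fraction_mean)
```

The first two calls print the fold-increases exactly as the isolate
characterization reports them; the invasion summary gives the percentage
of replicates in which the mutant lineage is still present after the
25th transfer, and the mean share of the bacterial population it holds
in those runs.

The numbered drivers under `analysis/` run the full narratives —
`01_simulate_community.py` (one serial-transfer run and its population
dynamics), `02_invasion_sweep.py` (the mixing x fold grid),
`03_flux_fit.py` (flux ratios across pathway fold-changes),
`04_phenotypes.py` (estimator recovery on synthetic plates and curves) —
and write their tables under `results/`.

There is also a CLI mirroring the drivers:

```sh
crossfeed simulate --seed 1 --out runs/
crossfeed sweep --mixing 0,1 --folds 1,2 --replicates 200 --seed 0 --outdir sweep/
crossfeed marge --model toy --expr expression.csv --out marge/
crossfeed phenotype growth --in od_curves.csv
crossfeed synth plate --seed 7 --out synth/
```

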