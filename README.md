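# opilio

Analysis toolkit for crossed ocean-acidification (OA) experiments on snow
crab (*Chionoecetes opilio*) embryos and larvae — and, more generally, for
any study design that crosses an early-life-stage exposure with a later
one and asks whether effects carry over.

OA experiments of this kind rear ovigerous females (and their embryos) at
several pH levels, then cross the hatched larvae over the same pH levels,
giving a 3 × 3 embryo-pH × larval-pH design with replicate "inserts" of
larvae per cell.  This package reimplements the complete computational
analysis of such a two-year experiment as a tested, reusable library:

* **Starvation-survival modelling** (`opilio.survival`).  Cumulative larval
  mortality is modelled with a power formulation of the logistic curve,

  $$P_m(t) = \frac{1}{1 + (t/t_{50})^{s}},$$

  where $t_{50}$ is the time to 50% mortality (the LT₅₀) and $s < 0$ a
  slope; this is the CDF of a log-logistic death-time distribution.  Both
  parameters may be constant or vary with embryo treatment (E), larval
  treatment (L), their sum (E+L) or their interaction (E#L); the ten
  candidate combinations are fitted by interval-censored maximum
  likelihood (deaths scored daily, censored at 7 weeks) and ranked by
  AICc with Akaike weights.
* **Permutation multivariate statistics** (`opilio.multivariate`):
  PERMANOVA (one or two crossed factors, optional permutation strata),
  PERMDISP, ANOSIM and SIMPER on z-scored Euclidean distances, written
  from first principles and cross-checked against scikit-bio.
* **Univariate framework** (`opilio.univariate`): one-way / two-way /
  nested ANOVA, Anderson–Darling and Levene checks, Tukey HSD with compact
  letters, and the gatekeeping rule that judges a term against the Levene
  p-value when variances are heterogeneous.
* **Reproductive metrics** (`opilio.reproduction`): percent area yolk,
  hatch counts from dry-mass or volumetric subsamples, fecundity and
  hatching-success percentages.
* **Seawater CO₂-system solver** (`opilio.carbonate`): pCO₂, carbonate
  speciation, total alkalinity and aragonite/calcite saturation states
  from a measured (pH_free, DIC) or (TA, DIC) pair, using the standard
  Lueker-set equilibrium constants.
* **Synthetic-data generators** (`opilio.simulate`): every input the
  analyses consume, generated at the study's design scale (9 cells ×
  5 inserts × 20 larvae; 15 larvae per treatment for morphometrics) with
  the statistical structure the analyses assume — no external data needed.

## Worked example

Simulate one design-scale survival experiment from the published year-1
best-fit parameters and rank the ten candidate models
(`python examples/01_survival_model_selection.py`):

```
           model  K     AICc  delta_AICc  weight
t50(E#L), s(E#L) 18 4628.535       0.000   0.992
     t50(E,L), s  6 4638.501       9.966   0.007
     t50(E#L), s 10 4641.476      12.941   0.002
       t50(E), s  4 4649.954      21.418   0.000
             ...
          t50, s  2 4671.536      43.000   0.000
```

The full-interaction model — both $t_{50}$ and $s$ free in every
embryo × larval cell, K = 18 parameters — carries essentially all the
Akaike weight (0.992), exactly the behaviour expected when the generating
process differs cell by cell.  The fitted Ambient/Ambient cell lands at
$t_{50} \approx 6.0$ d against a generating value of 6.20 d — sampling
error at 100 larvae per cell.

The other examples each cover one capability and print a short
interpretation line with their numbers:

| script | shows |
|---|---|
| `examples/01_survival_model_selection.py` | AICc ranking + per-cell LT₅₀ estimates |
| `examples/02_larval_morphometrics.py` | ANOSIM global R and SIMPER contributions |
| `examples/03_embryo_stage_anova.py` | nested ANOVA, assumption checks, Tukey letters |
| `examples/04_reproduction_metrics.py` | hatch-count estimators and clutch summaries |
| `examples/05_carbonate_system.py` | treatment water chemistry and saturation states |

A thin CLI wraps the same calls (`opilio simulate`, `fit-survival`,
`compare-models`, `anosim`, `simper`, `anova`, `clutch`, `carbonate`), and
`opilio run --config examples/demo_config.yaml --out results/demo`
executes the whole pipeline (simulate → model selection → multivariate →
ANOVA → carbonate) in a couple of seconds, writing the report tables and a
YAML manifest with the seed and config hash.

## Layout

```
src/opilio/        library (simulate, survival, multivariate, univariate,
                   reproduction, carbonate, recovery, io, pipeline, cli)
examples/          one narrative script per capability + demo pipeline config
tests/             pytest suite, including the acceptance checks
docs/methods.md    models, assumptions, numerical choices, limitations
scripts/           acceptance script
```
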