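# annoteq

Inequality analytics for gene-annotation databases.

Functional-annotation resources — Gene Ontology annotations, pathway
databases, drug-target tables, publication indexes — cover the genome very
unevenly: a few genes carry most of the annotations while thousands of
protein-coding genes are nearly blank.  `annoteq` is for computational
biologists and metascience researchers who want to quantify that
unevenness, model how it grows, and test whether the literature's
attention to disease genes tracks molecular evidence or annotation
richness.  It provides:

* **Inequality metrics** on per-gene annotation counts: the Gini
  coefficient

  `G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n Σᵢ xᵢ)`

  over the n genes with at least one annotation, plus Ricci–Schutz,
  Atkinson(ε), Kolm(κ), Theil entropy, CV, CV² and generalized entropy
  GE(α) — with record-resampling bootstrap confidence intervals.
* **GAF 1.0/2.x readers** with the standard curation filters (exclude
  IEA/ND/NR evidence, keep biological-process and molecular-function
  namespaces, count an assertion once across evidence codes), plus generic
  two-column gene/count tables for non-GO resources.
* **Rich-get-richer growth models**: seven weighting schemes
  (equal, initial, squared/cubic/exponential initial weight, squared
  weight, randomly focused initial weight) that redistribute each
  release's new annotations `n_{j+1}·p_gene` over the baseline genes;
  candidate models are ranked against the observed Gini trajectory by RMS
  distance via a statsmodels-style `AnnotationGrowthModel(...).fit()`.
* **Disease-gene concordance**: Spearman rank correlation between
  publication counts, expression effect-size FDR ranks and GO annotation
  counts (≥10-publication filter), and the fraction of published
  associations replicating at FDR 5%.
* **Synthetic generators** for GAF-like release series and disease-gene
  tables with tunable rank correlations, so every stage runs with no
  download.

## Worked example

```python
from annoteq import AnnotationGrowthModel
from annoteq.inequality import bootstrap_ci
from annoteq.growth import GrowthModel, GrowthModelSpec
from annoteq.synth import SynthGOAConfig, gen_goa_series

cfg = SynthGOAConfig(
    true_model=GrowthModelSpec(GrowthModel.squared_initial, stochastic=True, seed=1),
    seed=1,
)
series, truth = gen_goa_series(cfg)   # 17 releases, ~33k -> ~185k annotations

ci = bootstrap_ci(series.tables[-1], "gini", n_boot=1000, seed=1)
print(f"final Gini {ci.value:.4f} [{ci.ci_low:.4f}, {ci.ci_high:.4f}]")

results = AnnotationGrowthModel(series, seed=1).fit()
print(results)
```

prints

```
final Gini 0.4537 [0.4514, 0.4561]
Annotation growth-model comparison (17 versions; observed Gini 0.2501 -> 0.4537)
               model  distance  final_gini
     squared_initial  0.025496    0.433298
       cubic_initial  0.098930    0.583253
             initial  0.173803    0.250077
      squared_weight  0.271734    0.826668
initial_random_focus  0.315017    0.073057
         exp_initial  0.341266    0.044908
               equal  0.341283    0.044887
```

The synthetic archive starts at a Gini of 0.25 and rises to 0.45: the
annotation distribution becomes markedly *more* unequal even as total
annotations grow six-fold.  The ranking table compares that trajectory
with the seven growth models replayed from the same baseline and totals:
growth proportional to squared initial annotation share — strongly biased
towards already-annotated genes — fits best (lowest RMS distance), while
even growth (`equal`) and near-uniform exponential weighting would have
*reduced* inequality to 0.04 and rank last.

The same stages are scriptable from the shell:

```bash
annoteq synth goa-series --seed 1 --out-dir runs/goa
annoteq simulate --series runs/goa/series.tsv --seed 1 --out-dir runs/sim
annoteq gini --counts mycounts.tsv --metric all --bootstrap 1000 --out runs/gini.tsv
annoteq correlate --assoc assoc.tsv --min-pubs 10 --out-dir runs/corr
```

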