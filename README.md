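# herbdissect

Tools for dissecting how a plant's early transcriptome integrates the
separate components of insect herbivory.  When a chewing insect feeds, the
plant receives a bundle of stimuli at once: mechanical wounding, chemical
herbivory-associated cues (HACs) in the oral secretion, and cues from the
insect's orally secreted bacteria (OSB).  By comparing treatments that add
one component at a time — undamaged control, wounding (W+W), wounding plus
antibiotic-treated oral secretion (W+AB-OS), wounding plus intact oral
secretion (W+OS, "simulated herbivory") and actual herbivory — the
contribution of each component can be isolated.

`herbdissect` implements the full downstream analysis from a read-count
matrix, plus a negative-binomial simulator that plants known response
patterns so every stage can be validated against ground truth.

## The method

**Cumulative pattern classification.**  Three sequential differential-
expression contrasts follow the component chain (control→W+W, W+W→W+AB-OS,
W+AB-OS→W+OS).  Each contrast gives every gene a trichotomous call
d ∈ {−1, 0, +1} (DEG when |log₂FC| > 1.5 and BH-adjusted p < 0.05; genes
with mean read count < 10 are removed first).  The ordered triple of calls
is the gene's *pattern code*, one of 3³ = 27 patterns; pattern 1 = (0,0,0)
is "no response at any step".  Every non-null pattern with ≥ 300 genes
forms a *gene module*.

**Differential expression.**  A self-contained two-group NB Wald test:
median-of-ratios size factors, method-of-moments dispersions shrunk toward
a fitted trend φ(μ) = a₀ + a₁/μ, per-group log-link NB fits and an
asymptotic normal reference for the Wald statistic.

**GO functional network.**  Per-module hypergeometric over-representation;
the top 15 terms per module become nodes, joined when the Jaccard
coefficient of their gene sets exceeds 0.2:

    J(A, B) = |A ∩ B| / |A ∪ B|

Intramodular connectivity is the module mean of the node clustering
coefficient Cᵢ = 2eᵢ / (kᵢ(kᵢ−1)); extramodular connectivity is the summed
cross-module degree.  Modules are clustered (average linkage, 4 clusters)
on mean (1 − TOM) dissimilarity, with the unsigned topological overlap
TOM_ij = (l_ij + a_ij)/(min(kᵢ, kⱼ) + 1 − a_ij).

**Inducibility and similarity.**  Transcriptome inducibility per treatment
is the relative distance plasticity index over all control/treatment
replicate pairs, RDPI = mean over expressed genes of |x−y|/(x+y) ∈ [0, 1].
Treatment-to-treatment similarity (e.g. actual vs. simulated herbivory) is
quantified per GO term by the cosine of signed DEG vectors (+1/0/−1 per
gene) and globally by OLS regression of per-gene log₂ fold changes.

## Worked example

Run the whole pipeline on a synthetic experiment (5,000 genes, 4
replicates, the seven archetype patterns planted with |log₂FC| ∈ [2, 4]):

```sh
$ herbdissect run --seed 1 --outdir out/
report written to out/report.json
pattern 1: 2148/4817 (44.59%); modules: 7
```

Of the 4,817 genes passing the count filter, 2,148 (44.59%) show no
response at any component addition (pattern 1); the remaining responsive
genes resolve into exactly the 7 planted modules, and `report.json` records
a per-gene pattern-code accuracy of 0.9851 against the simulator's ground
truth, along with RDPI per treatment, the GO network statistics, the
4-cluster module grouping and the actual-vs-simulated herbivory regression
(recovered slope 0.7591 for a planted attenuation of 0.74).

The same arithmetic applied to a published-scale pattern table:

```python
>>> from herbdissect import summarize_counts
>>> summarize_counts(total=21466, pattern1=14566,
...                  module_sizes=[611, 929, 1620, 1051, 977, 815, 379])
{'total_genes': 21466, 'pattern1_genes': 14566, 'pattern1_pct': 67.86,
 'responsive_genes': 6900, 'module_sizes': [611, 929, 1620, 1051, 977, 815, 379],
 'modules_total': 6382, 'module_coverage_pct': 92.49}
```

i.e. 67.86% of tested genes are unresponsive and the seven modules cover
92.49% of the responsive genes.

Each stage is also exposed as its own subcommand (`simulate`, `de`,
`rdpi`, `patterns`, `enrich`, `network`, `similarity`) over TSV files, and
as plain library functions (see `docs/methods.md`).

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic benchmark from
the given seed and runs the complete pipeline end-to-end — simulation, QC,
RDPI, the three cumulative contrasts, pattern/module extraction, the GO
network and the similarity analyses — writing the results JSON to `--out`
and a one-line summary to stderr:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
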