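# afnet

Association of whole-blood gene expression with atrial fibrillation (AF)
and discovery of an AF-related subnetwork on a protein–protein interaction
(PPI) graph.

The package is aimed at analysts of family-based expression cohorts: it
implements the full chain from a features × samples log2 expression matrix
and a phenotype table to per-gene association statistics, FDR control, gene
scoring, greedy dense-module search on a PPI network, and pathway
enrichment of the merged subnetwork — plus a synthetic-data generator that
reproduces the statistical structure of such a cohort (pedigree clustering,
a minority prevalent-AF group, an incident-AF group under follow-up), so
that every stage can be exercised and validated without access to any
controlled cohort data.

## Models

**Prevalent AF (primary, cross-sectional).** For each gene *g*,

  y<sub>gi</sub> = β₀ + β<sub>AF</sub>·AF<sub>i</sub> + β<sup>T</sup>x<sub>i</sub> + b<sub>ped(i)</sub> + ε<sub>gi</sub>,  b ~ N(0, σ²<sub>f</sub>), ε ~ N(0, σ²<sub>e</sub>)

a linear mixed model of log2 expression on prevalent-AF status with a
Gaussian random intercept per pedigree (REML), adjusted for age and sex
(primary) or a full risk-factor panel (secondary). The AF coefficient, its
standard error, and a two-sided Wald p-value are reported per gene, with
Benjamini–Hochberg step-up adjusted q-values across the m genes tested.
Referents are participants who never developed AF.

**Incident AF (secondary, time-to-event).** Cox proportional hazards of
incident AF on expression as a continuous predictor, robust sandwich
standard errors clustered by pedigree, prevalent cases excluded.

**Medications.** The prevalent-AF model family with a dichotomous
medication flag (warfarin, beta blocker, digoxin, calcium channel blocker)
in place of the AF indicator.

**Gene scores and dense modules.** Each gene gets
z<sub>i</sub> = Φ⁻¹(1 − p<sub>i</sub>), the upper-tail normal quantile of
its association p-value. Starting from every scored gene as a seed, a
module grows by steepest ascent: the neighbouring gene that maximises

  Z<sub>m</sub> = (Σ<sub>i∈module</sub> z<sub>i</sub>) / √k

is added only if Z<sub>m</sub> strictly increases (k = module size); ties
break lexicographically; growth stops when no neighbour improves the score.
The top 1% of modules by score are merged, and the PPI edges induced on the
union form the AF subnetwork.

**Enrichment.** Hypergeometric upper-tail over-representation of
subnetwork genes in each gene set (universe = all scored network genes),
BH-adjusted across sets, with the conventional "k/K (ratio)" rendering.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (`scratch/synthetic_data/`, generated by the first script; small
result tables land in `results/`):

```
python analysis/01_simulate.py
python analysis/02_association.py
python analysis/03_network_modules.py
python analysis/04_enrichment.py
```

which prints (abridged):

```
cohort: 2000 samples in 700 pedigrees (144 prevalent AF, 116 incident AF, 1740 referents)
expression: 500 genes, 20 with a planted +0.15 log2 shift in prevalent AF (10 module genes boosted to +0.30)
prevalent AF (age+sex adjusted): 15 of 500 genes at FDR<0.05; 15/20 planted signal genes recovered
full risk-factor adjustment: 15 of 15 hits remain nominally significant (p<0.05)
incident AF (Cox, clustered robust SE): smallest q = 0.919 (0 genes at FDR<0.05)
500 modules grown (one per scored gene); top 1% = 5 merged
AF subnetwork: 16 nodes, 15 edges
planted module recovery: 10/10 members in subnetwork (Jaccard 0.62)
top set: SET000_planted  overlap 10/37 (0.27)  q = 4.16e-07
```

Reading: the mixed model recovers most of the planted over-expressed genes
at FDR < 0.05 and none of the null genes in excess; the greedy search then
pulls the full planted module into the merged subnetwork, and the gene set
constructed around that module dominates the enrichment table — the same
qualitative picture the analysis is designed to produce on real cohort
data. The incident-AF scan is expected to be null here because the
synthetic incident labels are independent of expression.

The same pipeline is scriptable end to end via the CLI:

```
afnet run-all --seed 0 --outdir run0          # simulate → … → enrich + manifest
afnet assoc --expression expr.tsv --phenotypes pheno.csv \
            --exposure prevalent --covariates age_sex --out assoc.tsv
```

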