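# soilsqi

Composite **Soil Quality Index (SQI)** computation and microbial-community
analysis for saline–alkaline revegetation trials.

Planting salt-tolerant forages (tall wheatgrass, chicory, alfalfa) is a
standard strategy for reclaiming saline–alkaline land. Judging whether it
works requires folding heterogeneous evidence — soil chemistry (SOM, AN, AP,
AK, pH, EC) and microbial alpha diversity (Chao1 richness, Shannon
diversity) — into one comparable score per treatment, and relating that
score to how strongly the soil microbiome restructured. `soilsqi` implements
that workflow end-to-end for soil scientists and microbial ecologists:

- **SQI core** — min–max membership functions, PCA factor-loading weights,
  and variance-contribution aggregation, as scikit-learn-style estimators;
- **chemistry statistics** — treatment summaries, one-way ANOVA, Tukey HSD
  compact letter displays, percent/fold change reports;
- **community diversity** — Chao1/Shannon/Pielou, Bray–Curtis, PCoA, RDA,
  Mantel tests, Spearman genus–environment panels, and the regression of
  community distance on SQI differences;
- **co-occurrence networks** — thresholded Pearson correlation graphs over
  top-abundance OTUs with a topology metric panel;
- **synthetic-data generator** — a Dirichlet-multinomial community and
  chemistry simulator emulating a 4-treatment × 3-replicate field trial, so
  every stage is testable without sequencing data.

## The index

For indicator $i$ with value $x_{ij}$, membership is min–max rescaled:

$$F(x_i) = \frac{x_{ij} - x_{i\min}}{x_{i\max} - x_{i\min}} \quad(\text{ascending: more is better})$$

$$F(x_i) = \frac{x_{i\max} - x_{ij}}{x_{i\max} - x_{i\min}} \quad(\text{descending: pH, EC})$$

PCA on the standardized indicator table yields, per retained component $j$,
the variance-contribution rate $K_j$ (percent) and per indicator the weight
$W_{ij} = C_{ij} / \sum_i C_{ij}$, where $C_{ij}$ is the absolute factor
loading (eigenvector entry × √eigenvalue). The index aggregates

$$SQI = \sum_{j=1}^{m} K_j \left(\sum_{i=1}^{n} W_{ij}\, F(x_i)\right),$$

so a perfect profile scores the cumulative contribution rate (a 0–100-point
scale) and entities can be ranked.

## Worked example

```bash
soilsqi run-all --seed 7 --outdir out/
```

or in Python:

```python
from soilsqi.pipeline import RunConfig, run

report = run(RunConfig(outdir="out", seed=7, permutations=199))
print(report["stages"]["sqi"]["sqi"])
print(report["stages"]["sqi"]["ranking"])
```

prints, for the default synthetic scenario:

```
{'CK': 11.44, 'GF': 63.44, 'JA': 98.1, 'CP': 63.83}
{'CK': 4, 'GF': 3, 'JA': 1, 'CP': 2}
```

The chicory treatment (JA) scores highest — it leads on SOM, AN, AK and
microbial richness while keeping pH and EC low — and the unplanted control
(CK) scores lowest, driven by its high salinity (EC), negligible available
phosphorus and depressed microbial diversity. The regression of pairwise
Bray–Curtis distance on pairwise |ΔSQI| is significant for both domains in
this run (bacteria: r² = 0.64, permutation p = 0.01; fungi: r² = 0.69,
p = 0.005), i.e. samples whose soil quality diverged most also restructured
their communities most. `out/` additionally holds the full audit trail:
memberships, loadings, weights, contribution rates, Tukey-lettered chemistry
summaries, alpha/beta diversity tables, ordination coordinates, Mantel
panels and network edge lists (TSV/GraphML) plus `report.json`.

Every stage is also available as a library function or a subcommand
(`simulate`, `chemistry`, `diversity`, `sqi`, `network`, `validate`), and
accepts user TSV inputs in place of the simulator (`--chemistry`,
`--community bacteria=path.tsv`).

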