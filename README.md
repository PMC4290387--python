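# epimarks

Quantitative analysis of how RNA polymerase II occupancy and four histone
modifications (H3K4me1, H3K4me3, H3K27ac, H3K27me3) near transcription start
sites relate to gene-expression variation, within and between closely related
species — the comparative-epigenomics setting of small primate cohorts
(3 species × 8 lymphoblastoid cell lines) profiled by ChIP-seq and RNA-seq.

The package is aimed at computational biologists who want a tested, fully
synthetic-data-exercisable re-implementation of this analysis stack:

* **Synthetic cohort generator** with recorded ground truth — latent mark
  levels with a realistic inter-mark covariance (H3K27me3 anti-correlated
  with the active marks), species-level shifts at a controllable fraction of
  genes, peak-caller-style outputs, read-count tables, chromatin-state
  segmentations.
* **Two-step enrichment classifier** — a stringent per-individual cutoff
  (FDR ≤ 5% for narrow peaks, domain score ≥ 20 for broad domains) seeds
  high-confidence regions; a relaxed cutoff (10–15%, or mere domain presence)
  is applied only at overlapping/orthologous positions, borrowing strength
  across individuals and species.
* **TSS quantification** — mark enrichment level
  `sqrt(input-subtracted RPKM / genome-wide average)` in windows from 2 kb
  upstream of the TSS to the earlier of 2 kb downstream or the second
  orthologous exon; expression level `log2(exon RPKM + 0.25)`.
* **Exhaustive-permutation differential test** — per gene, the t-statistic of
  the species coefficient (OLS with sex covariate) on double
  quantile-normalized values is compared against **every** species-label
  assignment (12,870 for 8+8; 6,435 for 8+7), with an empirical FDR from the
  permutation null.
* **Spike-and-slab Bayesian variable-selection regression (BVSR)** — MCMC
  over inclusion indicators with conjugate integration of coefficients,
  reporting posterior inclusion probabilities (PIP), posterior-mean
  coefficients, and the posterior of the proportion of variance explained.
* **Cross-validated variance partitioning** — 10-fold CV with 20 split
  replicates over marginal, first-order-interaction (31 features), and
  chromatin-state feature sets.
* **"Maximal" R²** — an errors-in-variables correction for measurement noise
  in both expression and mark levels,

  `R²_max = y'X (X'X − G·D)⁻¹ X'y / (y'y − G·σ²_y)`,

  with the noise variances `D`, `σ²_y` estimated from per-individual
  replicates as `σ̂² = (1/N²G) Σᵢ Σ_g (v_ig − v̄_g)²`.
* **Gaussian Bayesian network** over the five marks and RNA — BGe-scored
  hill climbing with a 1% per-edge sparsity prior and a blacklist forbidding
  RNA→mark edges.

## Worked example

```python
import numpy as np
import pandas as pd

from epimarks import SimulationConfig, simulate_cohort
from epimarks.synthetic import simulate_observed_matrices
from epimarks.association import build_features, cv_r2
from epimarks.constants import MARKS
from epimarks.differential import (
    PairwiseDesign, median_positive_filter, double_quantile_transform,
    permutation_de_test, classify_de,
)

cfg = SimulationConfig(n_genes=2000, n_species=2, seed=7,
                       emulate_missing_individual=False)
sample_table, gene_table, truth = simulate_cohort(cfg)
levels, expr = simulate_observed_matrices(truth, cfg)

# variance in expression explained by the five marks, within one species
h = np.flatnonzero((sample_table["species"] == "human").to_numpy())
per_gene = pd.DataFrame(levels[:, h, :].mean(axis=1),
                        index=truth.gene_ids, columns=list(MARKS))
res = cv_r2(expr[:, h].mean(axis=1), build_features(per_gene, "marginal"),
            model="ols", folds=10, replicates=20, seed=1)
print(f"within-species CV R^2 (5 marks): {res.mean_r2:.3f} +/- {res.sd_r2:.3f}")

# differential expression between the two species, exhaustive permutations
design = PairwiseDesign.from_sample_table(sample_table, "human", "chimpanzee")
matrix = pd.DataFrame(expr, index=truth.gene_ids, columns=truth.individual_ids)
kept = median_positive_filter(matrix, design)
de_res = permutation_de_test(
    double_quantile_transform(matrix.loc[kept], design), design)
de = classify_de(de_res, fdr_cutoff=0.05)
truth_pair = truth.pair_de_genes("human", "chimpanzee")
print(f"DE genes at 5% empirical FDR: {len(de)} "
      f"(of {len(truth_pair)} truly shifted; "
      f"{de_res.n_assignments} label assignments)")
```

Output:

```
within-species CV R^2 (5 marks): 0.582 +/- 0.001
DE genes at 5% empirical FDR: 154 (of 187 truly shifted; 12870 label assignments)
```

The generator's defaults place the latent variance explained at 0.58 within
species, so the cross-validated estimate of 0.582 ± 0.001 is a direct
parameter recovery; the permutation test finds most of the truly shifted
genes while the empirical FDR keeps false discoveries controlled.

## Command-line pipeline

```bash
epimarks run-all --outdir run1 --seed 1 --n-genes 2000
```

runs simulate → classify → quantify → de-test → associate → maximal-r2 →
bayesnet and writes each stage's tables (TSV/BED/JSON) plus a run manifest
with the configuration hash, per-stage seeds, and the gene/region counts
surviving every filter. Stages can also be run individually
(`epimarks simulate`, `epimarks de-test`, …) against an existing run
directory, so externally prepared fixtures can replace any upstream stage.

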