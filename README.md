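# scnoise

Quantification of residual biological gene-expression noise in local
neighborhoods of a single-cell RNA-seq manifold.

UMI counts of a gene across a homogeneous cellular neighborhood are modeled
as a Gamma–Poisson (negative binomial) mixture whose variance decomposes
into three parts:

    Var(x) = mu + mu^2 / r_t + eps * mu^2

* `mu` — Poisson sampling noise,
* `mu^2 / r_t` — shared total-UMI-count variability: per-cell size factors
  `beta_j = n_j / mean(n)` are fitted with a one-parameter Gamma(a, a),
  giving the technical dispersion `r_t = a`,
* `eps * mu^2` — residual biological noise, the quantity of interest.

`eps` is inferred per gene and neighborhood by MAP estimation under the NB
likelihood with dispersion `r_t / eps'` (`eps = (eps' - 1)/r_t >= 0`) and a
Cauchy(0, gamma) prior truncated to non-negative values. Neighborhoods are
defined by a pruned k-nearest-neighbor graph built from Pearson residuals
in a PCA space: candidate links are tested gene-by-gene against a local NB
background model and pruned when the top-3 geometric mean of
Bonferroni-corrected p-values falls below a threshold.

## Layout

| module                  | contents                                                             |
|-------------------------|----------------------------------------------------------------------|
| `scnoise.counts`        | MatrixMarket/TSV I/O, validation, dataset filtering                  |
| `scnoise.normalization` | depth offset models (Poisson GLM + LOESS, or analytic), Pearson residuals |
| `scnoise.graph`         | PCA elbow, k-d-tree knn, local backgrounds, link tests, Leiden/Louvain clustering, cluster transition probabilities |
| `scnoise.noise`         | size factors, Gamma dispersion fit, MAP/ML epsilon, cellular noise, gamma calibration |
| `scnoise.compare`       | differential-noise Wilcoxon tests, QP medoid mapping between datasets |
| `scnoise.simulate`      | synthetic neighborhoods with planted noise tiers and analytic ground truth |
| `scnoise.fish`          | smFISH spot-count noise estimator and nuclear/cellular noise ratios  |
| `scnoise.cli`           | `scnoise` command-line interface                                     |

## CLI

```sh
# simulate a homogeneous neighborhood with three noise tiers + ground truth
scnoise simulate --genes 2000 --cells 100 --seed 1 --out sim/

# full pipeline: filter -> normalize -> graph -> cluster -> noise
cat > config.yaml <<EOF
input: sim/
out: run/
min_cell_total: 1
min_gene_count: 1
min_gene_cells: 1
k: 25
gamma: 1.0
seed: 1
EOF
scnoise run --config config.yaml

# individual stages
scnoise graph sim/ --k 25 --prune-threshold 1e-3 --out graph/ --seed 1
scnoise noise sim/ --gamma 1.0 --out noise/ --seed 1
scnoise diff noise/ --clusters graph/clusters.tsv --group-a 1 --group-b 2 --out diff.tsv
scnoise fish-noise spots.tsv --method ml
```

Outputs are plain text: MatrixMarket epsilon matrix with gene/cell TSVs,
per-cell cellular-noise and technical-dispersion tables, edge/cluster/
transition tables, and the resolved run config.

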