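# tempshift

Gaussian-process model comparison for developmental time-course gene
expression. Given expression trajectories measured in two or more groups
(brain areas, disease status, species, ...) at possibly unmatched time
points, `tempshift` answers two questions per gene:

1. do the groups follow the **same shape** of trajectory at all, and
2. if so, is one group's trajectory a **temporal shift** of the
   reference's — and by how much (Δt)?

This separates changes in developmental *timing* (shift genes) from
changes in trajectory *shape* (DiffShape genes, e.g. cell-composition or
machinery changes), with no-shift genes as the null. Typical users are
transcriptomics groups analyzing developmental series such as
post-conceptional brain expression (time = log2 of post-conceptional
days).

## Model

Each gene's latent trajectory f is a zero-mean (after centering)
Gaussian process with squared-exponential kernel

    k(t, t') = σ_f² exp(−(t − t')² / (2 l²)),

observed with i.i.d. Gaussian noise σ. Three covariance structures over
the pooled samples of all groups are compared by exact marginal
likelihood:

- **independence** — groups are unrelated draws (block-diagonal
  covariance);
- **no-shift** — one shared trajectory at raw times;
- **shift** — one shared shape, group *i* evaluated at x_i − Δt_i
  (reference group: Δt = 0).

Each model's marginal likelihood is maximized over (σ_f, l, σ) — and Δt
for the shift model — by L-BFGS with analytic gradients and a ladder of
length-scale starts. Classification uses two log-likelihood ratios:

    LLRshape = log L(shift) − log L(independence)   (low  → DiffShape)
    LLRshift = log L(shift) − log L(no-shift)       (high → shift)

with either fixed thresholds (Λshape = Λshift = 50) or cohort-adaptive
cutoffs (DiffShape below mean − 2 sd of LLRshape; shift above the mean
with LLRshift > 10). Real-data workflows first keep temporally dynamic
genes by a cubic-regression filter (R² ≥ 0.5 of expression on time).

## Worked example

```python
import numpy as np, pandas as pd
from tempshift import TempShiftGP

rng = np.random.default_rng(0)
ta, tb = rng.uniform(5, 15, 60), rng.uniform(5, 15, 60)   # unmatched designs
X = pd.DataFrame({"time": np.r_[ta, tb],
                  "group": ["ctrl"] * 60 + ["case"] * 60})
y = np.r_[np.sin(2 * np.pi * ta / 10) + rng.normal(0, 0.3, 60),
          np.sin(2 * np.pi * (tb - 2.0) / 10) + rng.normal(0, 0.3, 60)]

est = TempShiftGP(reference="ctrl").fit(X, y)
print(f"dt(case)  = {est.shifts_[1]:.3f}")
print(f"LLRshift  = {est.llr_shift_:.1f}")
print(f"LLRshape  = {est.llr_shape_:.1f}")
```

prints

```
dt(case)  = 2.078
LLRshift  = 54.5
LLRshape  = 5.6
```

The case group's trajectory is recovered as the control trajectory
delayed by ≈ 2 time units (true value 2.0); LLRshift ≫ 0 says the shift
model beats the shared-trajectory null decisively, so this gene would be
called a shift gene, while LLRshape (shift vs independence) shows the
two groups do share one underlying shape.

The same analysis scales to tables through the CLI:

```sh
tempshift simulate --generator gp --groups 2 --seed 1 --out-prefix bench
tempshift fit --expr bench_expression.tsv --meta bench_metadata.tsv --out fits.tsv
tempshift classify --results fits.tsv --mode fixed --lshape 50 --lshift 50 --out labeled.tsv
```

All tables are TSV (`NA` for missing, gene column `gene_id`); results
files carry their run configuration as `#` header lines, and reruns
with the same seed are byte-identical.

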