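# metasig

Unsupervised extraction and analysis of **metabolite signatures** from
nonnegative abundance matrices, as produced by targeted LC-MS/MS profiling
of tissue in a two-group study design (e.g. a diet-induced metabolic
phenotype versus lean controls).

Given a metabolites × samples matrix `X ≥ 0`, the pipeline

1. factorizes `X ≈ W H` by multiplicative-update **NMF** (`W ≥ 0`:
   signature profiles, each column a weight distribution over metabolites
   summing to 1; `H ≥ 0`: per-sample signature loadings),
2. assesses the number of signatures by **consensus clustering** over
   random restarts, scored by the **cophenetic correlation coefficient** of
   the consensus matrix,
3. hierarchically clusters samples by their signature proportions and
   scores cluster–group agreement,
4. tests each signature's top-weighted metabolites for **pathway
   overrepresentation** (exact hypergeometric test, Benjamini–Hochberg
   adjustment) against a GMT library, and
5. compares metabolites between the two groups (pooled-variance Student t
   by default) with fold changes reported larger-over-smaller plus a
   direction flag.

A synthetic-data module generates studies with planted signatures,
group-linked signature dominance, multiplicative log-normal noise, planted
per-metabolite fold changes and matched pathway libraries, so every stage
can be validated against known ground truth. Its defaults emulate a
280-metabolite, 12-sample (6 + 6) cardiac metabolomics design with four
signatures.

The core objects follow scikit-learn conventions (`SignatureNMF` and
`ConsensusRankSelector` are estimators with `fit`, fitted attributes ending
in `_`, and `get_params`/`set_params`); module-level functions
(`factorize`, `select_rank`, ...) are thin wrappers over them.

## Worked example

```python
import numpy as np
from metasig import (StudyConfig, generate_study, select_rank, factorize,
                     cluster_samples, fold_change, reconstruction_error)

config = StudyConfig(noise_cv=0.1, planted_fold_changes=((0, 4.31),), seed=0)
matrix, truth = generate_study(config)           # 280 x 12, groups A/B

sel = select_rank(matrix, range(2, 8), n_runs=50, base_seed=0)
print({k: round(v, 3) for k, v in sel.cophenetic_by_k.items()})

fit = min((factorize(matrix, k=4, seed=s) for s in range(5)),
          key=lambda r: reconstruction_error(matrix, r))
ca = cluster_samples(fit.loadings, cut_k=2, groups=matrix.groups())
print("cluster purity:", ca.purity_by_group)

row = fold_change(matrix, reference="A").loc["M0001"]
print(f"M0001 fold change: {row['fold_change']:.2f} ({row['direction']}), "
      f"p = {row['p_value']:.2e}")
```

prints

```
{2: 1.0, 3: 1.0, 4: 1.0, 5: 0.996, 6: 0.994, 7: 0.993}
cluster purity: {'A': 1.0, 'B': 1.0}
M0001 fold change: 4.14 (up_in_A), p = 1.54e-02
```

The cophenetic curve is 1.0 through rank 4 — the consensus over 50
restarts is perfectly stable — and decays once extra components start
splitting noise. A two-way cut of the loading dendrogram separates the two
groups exactly (purity 1.0 for both), and the metabolite carrying a planted
4.31-fold group difference is estimated at 4.14-fold from six samples per
group with a significant t-test. See `docs/methods.md` for the model, the
generator's assumptions, and a structural caveat about smallest-tie
cophenetic rank selection on two-group designs.

The same stages are scriptable from a shell (`metasig simulate`,
`select-rank`, `factorize`, `cluster`, `enrich`, `diff`, `run-all`); each
`run-all` leaves a `manifest.json` recording config hash, seeds, per-stage
wall time and outputs.

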