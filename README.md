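# micdeg

Identification of differentially expressed genes (DEGs) by the **maximal
information coefficient (MIC)**, together with the simulation benchmark used
to characterize it: four-family expression simulators, SNR-controlled white
noise, ROC/AUC evaluation with noise-immunity slope analysis, a
continuous-to-count transformation for count-model tools, and an automated
density-distribution survey.

## Why MIC for differential expression?

There is no agreed parametric model linking a gene's expression vector
*g<sub>j</sub>* = (*g*<sub>1j</sub>, …, *g*<sub>Nj</sub>) to the sample
phenotype *T* = (*t*<sub>1</sub>, …, *t*<sub>N</sub>), *t<sub>i</sub>* ∈ {0
(control), 1 (case)}. MIC is a model-free association statistic: treating
(*T*, *g<sub>j</sub>*) as points in the plane, it grids the plane with every
*x*×*y* bin partition whose size satisfies *xy* ≤ B(*n*) and takes

> MIC(D) = max<sub>xy ≤ B(n)</sub> M(D)<sub>x,y</sub>,  
> M(D)<sub>x,y</sub> = max I\*(D, x, y) / log min{x, y},

where I\* is the largest mutual information over grids of that size and
B(*n*) = *n*<sup>0.6</sup> by convention (floored at 4 so the 2×2 grid is
always admissible). MIC lies in [0, 1]; genes are ranked by it, so any
monotone relationship with phenotype — not only a mean shift — is detected.
For small samples (n ≤ 30) the search is exact by full grid enumeration;
larger samples use the standard equipartition + dynamic-program
approximation.

The benchmark judges a score vector by the rank-based ROC AUC against the
simulation's ground-truth DE mask (0.5 = chance), and judges noise immunity
by fitting a least-squares line of AUC against noise level ℓ = 10 − SNR(dB):
|slope| ≤ 10⁻⁴ counts as horizontal (noise-immune); slope > +10⁻⁴ flags
anomalous behavior.

## Worked example

```python
import numpy as np
from micdeg import (builtin_design, generate_dataset, DatasetSpec,
                    mic_scores, roc_auc, noise_series, fit_noise_auc_line)
from micdeg.simulate import dataset_seed

group = [g for g in builtin_design() if g.group_id == "lognormal-2"][0]
ds = generate_dataset(group, DatasetSpec(n_genes=2000),
                      rng=dataset_seed(1, group.group_id, 0))
scores = mic_scores(ds.matrix, ds.phenotype)
print("median MIC (DE):     %.3f" % np.median(scores[ds.de_mask]))
print("median MIC (non-DE): %.3f" % np.median(scores[~ds.de_mask]))
print("ROC AUC: %.3f" % roc_auc(scores, ds.de_mask))

aucs = [roc_auc(mic_scores(d.matrix, d.phenotype), d.de_mask)
        for _, d in noise_series(ds, base_seed=1)]
fit = fit_noise_auc_line([10 - snr for snr in range(11)], aucs)
print("slope: %.4f category: %s" % (fit.slope, fit.category))
```

Output:

```
median MIC (DE):     0.311
median MIC (non-DE): 0.191
ROC AUC: 0.699
slope: -0.0055 category: negative
```

The 100 truly differential genes score visibly higher than the 1,900
background genes (AUC 0.70: a random DE gene outranks a random non-DE gene
70% of the time), and performance decays smoothly — not anomalously — as
white noise intensifies (negative slope).

The same pipeline is available from a shell:

```bash
micdeg simulate --group lognormal-2 --genes 2000 --seed 1 --out sim/
micdeg score sim/lognormal-2.rep0.matrix.tsv sim/lognormal-2.rep0.phenotype.tsv
micdeg evaluate --family lognormal --reps 10 --genes 2000 --seed 1 --out results/
micdeg survey sim/lognormal-2.rep0.matrix.tsv
```

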