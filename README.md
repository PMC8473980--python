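# hblup

Single-step genomic BLUP (HBLUP) for the joint genetic evaluation of
disconnected tree-breeding programs.

Commercial tree improvement programs run for decades on separate pedigrees.
When two programs share almost no recorded ancestry, their breeding values
cannot be compared, and neither program can predict how its parents would
perform in regions where only the other program runs trials.  Genotyping a
few hundred parents changes that: marker-based relationships among the
genotyped subset connect the pedigrees, and the single-step relationship
matrix **H** propagates that connectivity to every ungenotyped relative.
This package implements the full workflow for two multigenerational
*Eucalyptus*-style programs — pedigree and genomic relationship
construction, H assembly, REML mixed models across planting regions, and
the comparison of pedigree-only and single-step analyses — together with a
synthetic dual-program data generator used to validate every step against
known truth.

## The model

Phenotypes follow the individual-tree linear mixed model

```
y = Xb + Zu + e,          u ~ N(0, Σ_a ⊗ K),   e ~ N(0, R)
```

where `b` holds trial means, replicate effects, checklot means and
(optionally) founder-race genetic-group covariates; `u` holds additive
genetic effects with an unstructured covariance `Σ_a` across regions and a
numerator relationship matrix `K` that is either the pedigree matrix **A**
or the single-step matrix **H**; further independent random terms model
full-sib family (SCA) effects, open-pollinated family means, incomplete
blocks and row-plots with trial-specific variances.

The genomic layer follows the standard single-step construction:

* `G = ZZ′ / (2 Σ p_j(1−p_j))` with `Z = M − 2P` (VanRaden's first method),
  after a MAF ≥ 5 % filter and mean imputation;
* `G_a = a + bG` with `(a, b)` solving the two first-moment equations that
  match `G` to the pedigree block `A22` of the genotyped individuals;
* `G_w = 0.95·G_a + 0.05·A22` (blending, guarantees invertibility);
* `H` replaces the genotyped block of **A** with `G_w` and updates all
  relatives through the projection `A12 A22⁻¹`; its sparse inverse is
  `H⁻¹ = A⁻¹ + [0 0; 0 G_w⁻¹ − A22⁻¹]`.

Variance components are estimated by average-information REML on the dense
phenotypic covariance; breeding values, exact prediction error variances
(PEV), and accuracies `r = √(1 − PEV/σ²_a)` come from Henderson's
mixed-model equations with the sparse NRM inverse.  Narrow-sense
heritability and dominance proportions are

```
h² = σ²_a / (σ²_a + σ²_f + mean_k(σ²_bk + σ²_pk + σ²_ek)),    d² = 4σ²_f / (same)
```

with the mean over the trials of a region (or all trials).

## Worked example

```python
import numpy as np
from hblup import (SimulationConfig, simulate_dataset,
                   scenario_compare, comparative_findings)

cfg = SimulationConfig(seed=1)          # two programs, three regions
ds = simulate_dataset(cfg)

datasets = {p: (ds.pedigrees[p], ds.phenotypes[ds.phenotypes.program == p])
            for p in cfg.programs}
comp = scenario_compare(datasets, ds.markers, ds.genotyped,
                        joint_pedigree=ds.pedigree_joint,
                        true_bv=ds.truth.true_bv)

joint = comp.get("hblup-joint", "JOINT")
print(joint.h2_d2.round(3).to_string(index=False))
findings = comparative_findings(comp, list(cfg.programs))
for k, v in findings.items():
    print(f"{k}: {v:.3f}" if isinstance(v, float) else f"{k}: {v}")
```

prints (exactly, for this seed):

```
region    h2    d2  CVa
 GIPPS 0.313 0.032  NaN
    GT 0.239 0.038  NaN
    WA 0.147 0.065  NaN
delta_race_sigma2a: 0.107
acc_parents_correlated_joint: 0.389
acc_parents_correlated_within: 0.198
n_parents_correlated_cells: 5
```

The regional `h²` of the joint single-step fit sit at the low magnitudes
typical of growth traits.  `delta_race_sigma2a > 0` shows that dropping the
founder-race genetic groups reallocates race variance into the additive
component (the estimate is inflated without them).  The last three lines
compare prediction quality for *parents represented by progeny only in
other regions*: the correlation between their predicted and true breeding
values in the target region rises from 0.20 under within-program
single-step models to 0.39 under the joint analysis, because the joint
**H** lets one program's trials inform the other's parents.

A command-line interface mirrors the workflow:
`hblup simulate`, `hblup build-matrices` (A/G/H, conflict screen, founder
race summaries), `hblup fit`, `hblup compare`, `hblup report`.

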