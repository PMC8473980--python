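# Methods

This note documents the models, algorithms, numerical choices, and the
synthetic-data design behind `hblup`, and states what the test suite does
and does not demonstrate.

## Relationship matrices

**Pedigree.**  Pedigrees are parsed per program, namespaced
(`"EG1:P001"`), topologically sorted, and validated (unique ids, acyclic;
referenced-but-undefined parents are inserted as founders with an
`UNKNOWN_RACE` label and a warning).  Founders shared between programs are
collapsed through an alias table into single nodes.  Inbreeding uses the
Meuwissen–Luo ancestor traversal; **A** is built by the tabular method and
always carries inbreeding (`a_ii = 1 + F_i`), and **A⁻¹** by Henderson's
rules with Mendelian-sampling variances from parental inbreeding
(`d_i = 0.5 − 0.25(F_s + F_d)`, `0.75 − 0.25F` with one known parent, 1
with none).  An unknown parent contributes zero relationship and the
variance of an unrelated, non-inbred parent.  Race genetic groups are
realized as fixed-effect covariates from the founder-race fraction matrix
(founder rows are race indicators, descendant rows average their parents,
an unknown parent counts as `UNKNOWN_RACE`); **H** itself stays group-free.

**Genomic.**  Markers with MAF < 5 % (frequencies from the non-missing
calls of the currently genotyped sample) are removed and remaining missing
calls imputed to the marker mean `2p_j`.  **G** is VanRaden method 1.
Tuning solves the two-equation first-moment system matching
`mean(diag G) → mean(diag A22)` and `mean(G) → mean(A22)`, with the
overall means taken over all n² entries (this choice makes the two
equations independent); the tuned matrix is blended,
`G_w = 0.95 G_a + 0.05 A22`.  Blending is the only invertibility guard —
no eigenvalue bending is applied.  SNPs and small INDELs are treated
identically; no per-individual call-rate filter is applied by default.

**Single-step.**  **H** is assembled in both published layouts (the
additive-correction form and the direct form); the two agree to 1e−10 and
the unit tests assert it.  `H⁻¹ = A⁻¹ + [0 0; 0 G_w⁻¹ − A22⁻¹]` is kept
sparse outside the genotyped block.  When `G_w = A22`, `H ≡ A` and
`H⁻¹ ≡ A⁻¹` exactly, which is also the degenerate path taken when a
dataset has no genotypes.

**Conflict screening.**  Pedigree errors are flagged from the *raw* (un-
tuned) G, since parentage logic lives on the identity-by-state scale: any
genotyped pair (or diagonal) with `|G − A22| ≥ 0.35` is reported, with
parent–offspring contradictions sorted first.  The 0.35 default sits
between the half-sib (0.25) and parent–offspring (0.5) expectations; note
that a false parent who is a close relative of the true parent produces a
smaller deviation and can escape any fixed threshold.  The screen's
operating point (sensitivity ≥ 0.9 at a 5 % error rate, FPR ≤ 1 %) is
demonstrated for errors that substitute an unrelated individual.
Confirmed conflicts are corrected by dropping the contradicted parent link
(no parentage search), after which H construction is repeated.

## Mixed models and REML

The design machinery builds `X` (overall mean or trial means, replicate-
within-trial contrasts, one column per checklot, optional race-fraction
covariates with the largest-share race as reference) and the random terms:

* additive — records map to pedigree individuals; with
  `region_structure="unstructured"` the additive covariance is a full
  `Σ_a` across regions (region-as-trait layout: every tree is recorded in
  one region, cross-region information flows through the NRM and `Σ_a`);
* family — one level per unordered parent pair and region, variances
  shared or grouped by trial groups (default: a single group);
* open-pollinated family means — their records are deliberately excluded
  from the additive term and absorbed by this factor;
* incomplete block, row-plot, residual — trial-specific variances.

REML maximizes the restricted likelihood of the dense phenotypic
covariance `V = Σ_i θ_i V_i` by average-information updates.  Parameters
are transformed: log variances, and the spherical (angle) parametrization
of the Cholesky factor of `Σ_a`, with angles boxed to `[0.05, π − 0.05]`
so that correlations live strictly inside (−1, 1); a correlation estimated
at the boundary surfaces as an active box bound rather than a numerical
ridge.  Safeguards: parameters at a bound with inward gradients are frozen
per iteration (active set), non-PD AI matrices are ridge-damped, steps are
halved until the likelihood does not decrease, and a full accepted step is
opportunistically doubled while it keeps paying.  Convergence requires
`|Δloglik| < 1e−6` together with a small parameter change, or three
consecutive likelihood-flat iterations (parameters can drift indefinitely
along flat directions such as the angles of a collapsed variance row).
Variances are floored at `1e−8 ×` the phenotypic variance.  Analytic
gradients are verified against central finite differences in the tests.

EBVs, exact PEV, and accuracies come from Henderson's equations with
`Σ_a⁻¹ ⊗ K⁻¹` in the additive block, solved by dense Cholesky; the PEV
diagonal is taken from the exact inverse of the coefficient matrix
(LAPACK `dpotri`), not from the row-wise approximations used by commercial
REML software — exact PEV are never larger, so accuracies can differ
slightly from approximated ones.  Accuracy is `√(1 − PEV/σ²_a)`, clipped
to [0, 1] with a warning.  AIC is `−2·loglik + 2·(number of free variance
parameters)`; REML likelihoods condition on the fixed design, so AIC is
only comparable across fits with identical fixed effects — comparisons
between models with and without race covariates carry that caveat.

## Two-stage flow and scenarios

Stage one fits each trial separately (pedigree NRM, race groups) and
subtracts the replicate estimates and the block and plot BLUPs from the
phenotype.  The additive variance used to standardize each trial to mean
zero and additive SD one is taken from a preliminary cross-site fit of the
adjusted data (one pooled additive variance, trial-specific environmental
variances): single-trial additive variances at a few hundred trees per
trial have a boundary-heavy sampling distribution (estimates of exactly
zero are common), and the pooled estimate is the stable choice; the
single-site estimates remain available (`sigma2a_source="single-site"`)
and serve as the fallback when the pooled estimate itself is at the floor.
Trials whose standardizing variance is at the floor are excluded with a
warning.

Stage two fits the standardized data under four scenarios — ABLUP with
race-fraction covariates, ABLUP without, within-program single-step HBLUP,
and joint HBLUP over both programs — on identical phenotype rows within a
comparison.  Each pedigree individual is classed per region: parents with
recorded progeny in the region ("parents represented"), parents with
progeny only elsewhere ("parents correlated"), genotyped individuals
without progeny with/without pedigree links, and recorded progeny.  Two
accuracy summaries are produced: the theoretical PEV-based accuracy per
class, and (when simulated truth is available) the empirical accuracy —
the correlation between predicted and true breeding values.  Theoretical
accuracies are not comparable across fits that estimate different `σ²_a`
(the ratio `PEV/σ̂²_a` moves with the scale), so model comparisons use the
empirical measure; for models with race covariates the estimated group
effects are added back first, because such models predict within-race
deviations while total merit includes the race mean.

## Synthetic data

The generator emulates two disconnected breeding programs at desk scale.
Defaults (all configurable): eight native races with Balding–Nichols
drift `Fst = 0.15` around ancestral frequencies `U(0.1, 0.9)`; programs of
40 and 32 founders with different race compositions; four founders known
to be shared; six *cryptic duplicate* founders (the same native tree
sampled by both programs under different local ids — identical genomes
and breeding values, unconnected pedigrees) plus four cryptic full-sib
founder pairs, so the cross-program block of G contains coefficients up
to ≈ 0.5 discoverable only from markers; an open-pollinated first
generation (unknown pollen parents drawn from the mother's stand, i.e.
her race frequency) followed by two full-sib generations mated within
selected parent pools (heavy parent reuse); 2,000 unlinked candidate-gene
markers gene-dropped through the pedigree with 2 % missingness, genotyping
80 % of the progeny-tested parents plus pedigreed-but-unplanted selections
and unpedigreed "others"; trials in three regions (one program absent from
one region), four replicates of contiguous family row-plots in incomplete
blocks, families deployed to two trials with a 60 % chance of staying in
one region; checklots as unpedigreed fixed entries.

True breeding values are polygenic and pedigree-driven (markers inform
relationships only): founders draw race shifts — correlated 0.7 across
regions, since race performance interacts with region — plus individual
deviations from `Σ_a` (σ²_a = 1 per region, r_a = 0.7); offspring take
parent means plus Mendelian deviations scaled by parental inbreeding.
Family effects (σ²_f = 0.2), block (0.4), plot (0.6) and residual (4.47)
variances give h² ≈ 0.15 and d² ≈ 0.12 on the standardized scale, the
magnitudes typical of eucalypt growth traits.  Pedigree errors substitute
a random *unrelated* earlier-born individual for the recorded sire and are
written to the truth log.  All randomness derives from one master seed via
stable per-stage hashing; identical configurations reproduce identical
datasets byte for byte.

What the generator does **not** emulate: linkage and LD between markers
(irrelevant for relationship estimation at candidate-gene density),
selection across generations, spatial field trend beyond blocks/plots,
genotype-by-environment structure beyond the regional correlation, trait
networks (wood properties are not derived from cores/NIR — phenotypes are
simulated directly), and checklot-specific residual variances.  Passing
tests therefore validate the algebra, the estimation machinery, and the
qualitative behavior of the comparisons — not field-data performance.

## Problem sizes and known limitations

The default dataset (~2,100 records, ~2,100 pedigree members, 74 genotyped)
was chosen so that the full four-scenario comparison runs in a few minutes
on one core while keeping each individual-class large enough for the
directional comparisons to be statistically meaningful; the REML-recovery
checks run twenty reduced single-program replicates.  Dense-V REML scales
as O(n³) per iteration, so analyses beyond ~5,000 records per fit would
need the sparse MME-based REML path that commercial tools use.  Estimates
of `Σ_a` for region pairs connected by few trials are noisy at this scale
and can reach the correlation bounds; they are reported as estimated.
Single-trial additive variances are boundary-heavy (see above).  The
conflict screen cannot see substitutions by close relatives of the true
parent.  Metafounders and genetic groups inside H, automatic parentage
reassignment, dominance genomic matrices, and spatial residual models are
out of scope.
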