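# Methods

## The question and the design

When an ancestral population colonizes a stressful environment, its gene
expression shifts plastically; as descendants adapt, expression shifts again
genetically. `plastevol` quantifies the relationship between those two
shifts, per gene, in a replicated ecotype design: two independent
geographic pairs, each consisting of a derived tolerant population (T1, T2;
e.g. metal-mine ecotypes) and its closest sensitive relative (S1, S2;
coastal ecotypes) standing in for the ancestor. Clones of each genotype are
assayed under a benign control (C) and a stress (Z, zinc) treatment, so
every genotype contributes one sample per treatment and within-genotype
pairing can absorb genetic differences between individuals.

Three group means per gene, on a variance-stabilized log2-like scale,
summarize the trajectory:

- `L_o` — sensitive populations in control (ancestor at home),
- `L_p` — sensitive populations in stress (ancestral plastic response),
- `L_a` — tolerant populations in stress (derived, adapted state).

The plastic change is `PC = L_p − L_o`; the evolutionary change is
`EC = L_a − L_p`; by construction `PC + EC = L_a − L_o`. Genes with
substantial PC and EC (see gating below) are classified:

- **reinforcement** — `EC·PC > 0`: evolution continued in the direction of
  the ancestral plasticity;
- **overshooting** — `EC·PC < 0` and `|EC| < r·|PC|`: plasticity overshot
  the new optimum and evolution trimmed it back;
- **reversion** — `EC·PC < 0` and `|EC| > r·|PC|`: evolution mostly or fully
  undid the ancestral response.

with ratio `r = 0.5` by default (`overshoot_ratio`). Reinforcement and
overshooting both imply the ancestral plasticity pointed toward the new
optimum; reversion implies it was maladaptive. Boundary handling is
explicit because noisy estimates do land on boundaries: `EC·PC = 0` carries
no directional information and is left unclassified; `|EC| = r·|PC|` is
assigned to reversion, the dominant class, by default (`boundary_tie`,
configurable to `overshooting` or `unclassified`).

## Differential-expression engine

The engine is intentionally compact NB machinery whose only job is to make
the calls the downstream logic consumes; every piece is replaceable via
config.

**Normalization.** Median-of-ratios size factors: the per-sample median of
`count / geometric-mean` over genes with strictly positive counts
everywhere. The median is taken on the ratio scale. Size factors enter the
GLMs as offsets, never by dividing counts.

**Dispersion.** Per-gene raw dispersion by pooled method-of-moments over
the population × treatment replicate groups, `α̂ = Σ(nⱼ−1)(vⱼ−mⱼ) /
Σ(nⱼ−1)mⱼ²`, floored at 0. A mean–dispersion trend `α(μ) = a₀/μ + a₁` is
fitted by trimmed non-negative least squares over all genes (zeros
included; three trimming passes at 3 SD). The working dispersion is a
log-scale weighted average of raw and trend values
(`dispersion_shrink_weight`, default 0.5). With 8 groups of 3 this gives
~16 residual degrees of freedom per gene before shrinkage; the trend
borrows strength across genes exactly where per-gene moments are noisy.

**Variance stabilization.** `vst = log2(normalized count + c)` with
`c = 1/(4·a₁)` clipped to [0.5, 32]. For an NB family this pseudocount
makes the variance of the log approximately mean-independent at large
means; the SD-versus-mean slope is checked to be ≈0 over the upper half of
the mean range in the tests. The transform is monotone in counts, and the
L-levels and PCA both use it.

**GLMs and tests.** Per-gene NB GLM, log link, fixed final dispersion,
fitted by IRLS. One design matrix is shared by all genes, so the normal
equations are solved as a single batched (genes × p × p) system; a run
over ~28k genes takes seconds. Four parameterizations cover all contrasts:
a combined population+treatment factor (between-population contrasts within
a treatment), population + population:individual + population:treatment
(genotype-paired within-population zinc responses), the same with ecotype
in place of population (the pooled sensitive/tolerant zinc response), and a
combined ecotype+treatment factor (tolerant vs sensitive in zinc).
Individual effects use sum-to-zero coding nested in their population (or
ecotype) so the designs stay full rank. Wald p-values come from
coefficient/SE against the standard normal; BH correction is applied across
genes per contrast, with non-converged genes excluded and reported as NA.
Measured on null simulations (2,000 genes, n = 3 per cell), the raw-p
rejection rate at 0.05 is 0.053–0.070 — the mild anti-conservatism expected
of small-sample Wald tests.

**Fold-change shrinkage.** Reported `lfc_shrunk` is the posterior mean
under a zero-centred normal prior whose variance is the empirical variance
of raw LFCs minus the mean squared SE (floored at 10⁻⁶):
`shrunk = raw · v/(v + se²)`. This pulls noisy estimates toward zero and
never increases magnitude. |FC| similarity summaries use the median of
absolute shrunken LFCs, since their distribution is strongly right-skewed.

Deliberately **not** implemented: Cox–Reid ML dispersions, adaptive-prior
shrinkage, independent filtering, and count-outlier replacement. The
low-count filter (row sum < `low_count_min`, default 10, across all
samples) is the only pre-filter; "across all samples" is read as the total,
which is the more permissive reading of an ambiguous phrase and is
configurable.

## Gating, gene sets and assimilation

Spuriously tiny PC or EC would otherwise scatter genes across categories,
so classification is gated on two pooled contrasts chosen for power:
substantial PC requires significance in the pooled sensitive
control-vs-zinc contrast; substantial EC requires significance in the
pooled tolerant-vs-sensitive contrast in zinc (both at `fdr_threshold`,
default 0.05).

- **CEC genes** (parallel constitutive evolutionary change): significant
  tolerant-vs-sensitive difference in the *control* treatment in both
  pairs, same direction.
- **DP genes** (derived plasticity): significant zinc response in both
  tolerant populations, same direction, plus an ecotype difference
  (control or zinc) in *each* pair. Direction consistency is not demanded
  of the ecotype component (the source description is silent there).
- **Canalized**: CEC genes no longer zinc-responsive in either tolerant
  population but with substantial ancestral PC.
- **Assimilated**: canalized genes whose ancestral plasticity pointed at or
  beyond the new optimum — no substantial residual EC, or category
  reinforcement/overshooting. `assimilated ⊆ canalized ⊆ CEC` holds by
  construction.

Overlap enrichment uses the one-sided hypergeometric tail with the
conditional-MLE odds ratio (sample OR reported alongside). The shared count
entering the table is the direction-consistent one; in degenerate settings
(e.g. FDR ≈ 1, every gene significant) that table can become inconsistent
and the overlap test is reported as null rather than fabricated. Category
proportions between gene sets are compared with exact two-sided binomial
tests (minimum-likelihood two-sidedness); |FC| distributions with Wilcoxon
tests, BH-corrected per comparison family.

## Parametric bootstrap and the shared-L_p bias

`L_p` appears in PC with a plus sign and in EC with a minus sign, so
measurement error in `L_p` makes the two estimates anti-correlated
(corr = −½ when group-mean errors are exchangeable), biasing classification
toward counteracting categories for noise-dominated genes. Each bootstrap
replicate therefore draws group means from `N(mean, SD/√n)` — with **two
independent** draws of the sensitive-zinc mean, one used in PC*, one in
EC* — and re-classifies; support is the fraction of replicates agreeing
with the point classification, and calls pass at
`bootstrap_support_threshold` (default 0.95; not stated in the source
material, so the raw support is always reported and any threshold can be
re-applied). The naive single-draw scheme is retained behind
`shared_lp_bootstrap` for comparison: at a pure-noise gene it classifies EC
as counteracting PC in ~⅔ of replicates versus the correct 50%, and for a
gene with true EC = 0 the two-draw scheme's counteracting frequency is 0.5
exactly by sign symmetry. Zero SDs degenerate to noise-free draws (support
1); the noise model is normal on the VST scale, which is designed for
approximate homoskedasticity.

## Synthetic data: what it emulates and what it does not

The generator reproduces the design (4 populations × 2 treatments ×
`n_individuals` genotypes, clones paired across treatments), log-normal
library depths (`libsize_sigma`, default 0.15), per-genotype log2 offsets
shared between a genotype's two samples (`genotype_sigma`, default 0.1),
gamma-distributed NB dispersions (`dispersion_mean` 0.05,
`dispersion_shape` 2), and log2-normal baselines (mean 6, SD 1.5, clipped
to [1, 14] — tens to hundreds of counts for most genes, as in a ~25M-read
bulk experiment). Four gene classes with effect magnitude `lfc_scale`
(default 2) and random ±1 directions:

- `stress_reverted` (30%): sensitive-only zinc response; truth class
  reversion (EC = −PC). This is the dominant ancestral stress response that
  adapted populations have lost.
- `cec` (1.5%): constitutive ecotype shift (±lfc in both treatments, both
  pairs); half (configurable) also get a half-sized sensitive zinc response
  in the same direction — beneficial ancestral plasticity, truth class
  reinforcement — feeding the canalization/assimilation path.
- `dp` (0.5%): tolerant zinc response of ±lfc centred on baseline (control
  −lfc/2, zinc +lfc/2), giving a constitutive ecotype offset in both
  treatments; 83% also ancestrally plastic with a 0.8·lfc sensitive
  response, making their truth class overshooting. Cell levels are centred
  so no class displaces expression more than one `lfc_scale` from baseline;
  an early stacked design pushed down-regulated DP genes below one expected
  count, which makes them uncallable by any method.
- `null` (remainder): pure noise.

The truth table stores the noise-free levels and the class implied by the
same inequalities the classifier uses (oracle self-consistency is tested).
Not emulated: gene–gene correlation, isoforms, batch/tank effects, GC or
length biases, outlier counts. Passing recovery tests therefore show the
pipeline's statistics behave as designed under its own assumptions, not
that real data meet those assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run simulations of 1,200–3,000 genes —
large enough for stable BH behaviour and trend fitting, small enough that
the full suite finishes in well under a minute; the pipeline itself is
vectorized and handles transcriptome scale (~28k genes) in seconds. IRLS
runs at most 60 iterations to an absolute coefficient tolerance of 1e-8
with a 1e-10 ridge; means are clipped to [1e-10, 1e12]; genes with all-zero
rows or non-converged fits get NA p-values and are excluded from BH
denominators. PCA is a centred (unscaled) SVD over samples with signs fixed
by the largest-magnitude coordinate. All randomness flows from explicit
seeds (`rng_seed` in the config and generator); identical seeds give
byte-identical outputs.

## Known limitations

The engine's simplifications (moment dispersions, normal-prior shrinkage,
closed-form VST) will not numerically match the published heavyweight
implementations gene-for-gene; medians of |FC| may shift slightly under a
different shrinkage prior. The substantiality gates tie classification to
pooled-contrast power, so category proportions depend on sample size in the
same way the source analysis does. The bootstrap treats group means as
normal with known SDs; an NB resampling alternative would be stricter at
very low counts.
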