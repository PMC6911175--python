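# Methods

`cistrome-ess` analyses pooled CRISPR knockout screens that target
transcription-factor binding sites ("cistrome screens") rather than genes.
This note documents the models the package implements, the synthetic data it
validates itself on, the parameters that matter, and the design choices made
where the design was genuinely open.

## Screen model and selection estimation

A screen measures, for every guide RNA, a day-0 count and one or more
endpoint counts after several weeks of growth. Counts are modelled as
negative binomial with variance `mu + alpha*mu^2`; NB is the standard
assumption for pooled screen counts and the default dispersion here is
`alpha = 0.1`. Selection acts exponentially on clone abundance: a site with
per-generation selection coefficient `beta` changes its guides' expected
abundance by `2^(beta*G)` over `G` effective population doublings. The
default `G = 10` corresponds roughly to a four-week screen; published
screen tables rarely state `G`, so it is a configurable scale and only
rank- and sign-based conclusions are treated as transferable.

Estimation proceeds in the order a MAGeCK-style analysis would:

1. **Normalisation** — median-of-ratios size factors over guides with
   nonzero counts in every sample, rescaled so the day-0 reference has
   factor 1; a pseudocount of 0.5 guards the logarithms and is negligible
   at screen depth.
2. **Guide log2 fold change** — `log2(mean endpoint) − log2(mean day-0)` on
   normalised counts.
3. **Beta-score** — per site, the 10%-per-tail trimmed mean of guide LFCs
   divided by `G`. Negative beta = depleted = essential. The trimmed mean
   replaces the original maximum-likelihood estimator of the MAGeCK-VISPR
   family: it preserves the "beta behaves like a log fold change" semantics,
   is robust to a few inert guides, and is fully specifiable without the
   joint likelihood.
4. **Copy-number correction** — each site takes the copy number of the
   segment containing its summit; a least-squares line `beta ~ copy_number`
   fitted over all sites is subtracted and re-added at diploid. Multi-cut
   toxicity makes amplified loci look depleted regardless of function; the
   linear trend removal is the simplest correction that makes diploid sites
   invariant and removes the monotone confounding. With a single copy state
   the adjustment is the identity.
5. **Significance** — a permutation null resamples site-sized guide sets
   (with replacement) from the AAVS1 safe-harbor control guides and applies
   the same trimmed-mean statistic; p-values are two-sided with the +1
   correction, and FDR is Benjamini-Hochberg. In the full chain the test is
   applied to the **CNV-adjusted** beta (rescaled to LFC units): testing the
   raw beta would flood the hit list with amplification artifacts, which is
   precisely what the correction exists to prevent. `neg_rank` orders sites
   by ascending adjusted beta (1 = most depleted).
6. **alpha-RRA** — guides are ranked genome-wide by LFC (most depleted
   first) and ranks normalised to (0,1) by `rank/(n+1)`. For a site with k
   guides whose sorted normalised ranks are `r_(1) <= ... <= r_(k)`, the
   score is `min_j P(U_(j) <= r_(j))` over the guides with `r_(j) <
   alpha` (default 0.25), where `U_(j)` is the j-th order statistic of k
   uniforms (a Beta(j, k−j+1) probability). Smaller scores mean stronger
   concerted depletion. A permutation p-value redraws same-sized guide sets.
   Note the truncation leaves an atom of scores at 1.0 (sites with no
   alpha-passing guide), so null permutation p-values are exactly uniform
   only at `alpha = 1`; at smaller alpha they are conservative, which the
   tests assert separately.

### Calibration of the control-based null

All sites share a single resampled control pool, so the realised fraction of
null sites with p < 0.05 fluctuates with the sampling noise of the pool's
tail quantiles, not just binomial noise. Estimating the 5% tail of trimmed
means of 16 draws requires a pool much larger than a typical library's
negative-control arm; the package's calibration benchmark therefore uses a
null screen with a 2,000-guide neutral arm and 2,000 permutations. This is a
measurement-precision choice — library manifests keep their design-scale
control counts (267 AAVS1 guides per library).

## Synthetic screens

The simulator generates everything downstream analysis consumes, with every
random draw taken from a stream derived from `(master seed, operation
name)`, so any stage reproduces exactly in isolation.

* **Genome annotation** — by default two 30-Mb chromosomes; genes with a
  10% strongly depleting minority (`beta_gene ~ N(-1, 0.3)` vs `N(0, 0.3)`)
  so a bottom decile with clear essential character exists; binding sites
  drawn per selection class, with the proximity class placed within 50 kb
  of bottom-decile gene TSSs; TAD boundaries, loop-anchor intervals with
  head-to-head orientation flags, and copy-number segments (1-4 copies)
  tiling each chromosome.
* **Features** — signal features (DNase, H3K27ac, H3K4me2, FOXA1, CTCF, ER)
  are log-scale Gaussian around a shared baseline; a latent essential set
  receives per-feature mean shifts. Annotation features (TSS distance,
  nearest-gene expression and essentiality, copy number, motif presence)
  derive from the fixture. Nearest gene = minimal |TSS − summit|, ties to
  the lower coordinate.
* **Ground truth** — `beta_true = intercept + sum w_f x_f + noise`, shifted
  by its prevalence quantile so a chosen fraction (default 5%) is negative.
  The positive branch is then compressed by `positive_scale` (default
  0.05): the uncompressed linear score would put nearly every non-essential
  site under strong positive selection, which neither matches screens (the
  background is neutral) nor permits the |LFC| < 0.1 nonessential labeling
  rule to fire. The compression is strictly monotone, so rank-based
  recovery statistics are unaffected; `positive_scale=1` restores the pure
  linear model. A hard truncation to zero was rejected because massive ties
  at zero make rank-agreement metrics uninformative (a perfect estimator
  would cap near Spearman 0.38 at 5% prevalence).
* **Counts** — day-0 means are lognormal around the depth (default 500
  reads/guide, sigma 0.25, a typical well-covered screen); endpoint means
  are scaled by `2^(beta_eff*G)` with
  `beta_eff = beta_true + cnv_effect*(copies − 2)` (default −0.1 per extra
  copy). Two endpoint replicates by default. AAVS1 guides are neutral;
  essential-gene positive controls draw `beta ~ N(-0.5, 0.1)` per gene.
* **SNP catalogs** — trait SNPs land inside binding-site intervals sampled
  proportional to length, with essential (beta_true < 0) enhancers
  up-weighted by the trait's fold; positions are emitted 1-based.

What the simulator does **not** emulate: sequence composition (no PAM sites
or FASTA in synthetic mode), guide-efficiency heterogeneity, chromatin-
accessibility effects on Cas9, linkage disequilibrium between SNPs, and
Hi-C-derived contact structure beyond interval annotations. Passing
recovery tests therefore demonstrates the estimators' correctness under the
stated statistical structure, not performance on any real screen.

## Library design

Candidate guides are scanned inside each site (NGG on either strand in
sequence mode, cutting 3 bp 5' of the PAM — the standard SpCas9 blunt-cut
convention — or an injected pool in synthetic mode), filtered on pluggable
efficiency/specificity scores (the thresholds are configuration, since no
particular scoring algorithm is canonical), and the k guides nearest the
peak summit are kept (default k = 20; ties to the lower coordinate, then +
strand). Paired guides for deletion screens are chosen from pools flanking
the site and ranked by total flanking distance, so the smallest deletions
containing the whole site come first (up to 25 pairs per site). When a
library is built to an exact guide total, per-site counts are apportioned
within [12, 20]. Control arms add essential-gene-targeting guides (5 per
gene) and AAVS1 negatives.

## Feature association

Signal features are window means over tracks: 150 bp centered on the
summit, widened to 300 bp for histone modifications (broader marks),
clipped at chromosome ends, uncovered bases reading 0. The feature ranking
compares the lowest `top_frac` (default 5%) of sites by adjusted beta
against the rest with a two-sided Mann-Whitney U test per feature and cell
line, averages p-values arithmetically across cell lines, and sorts
ascending; direction is the sign of the median difference, and constant
features are flagged with p = 1. Proximity enrichment tests the 2x2 of
essential/non-essential sites near/far from bottom-decile-beta gene TSSs
(default 100 kb) with Fisher's exact test. Site-class comparisons use
two-sample Kolmogorov-Smirnov on beta distributions; "strongest" sites
default to the top signal decile. TAD-boundary membership is a summit
within ±10 kb of a boundary midpoint; anchor membership is a summit inside
a head-to-head anchor interval; both are compared in-vs-out by
Mann-Whitney, and essential sites inside vs outside anchors are contrasted
on H3K27ac. Essential-site sets for these analyses use the screen threshold
FDR < 0.25 with beta < 0.

## Essentiality prediction

Labels: essential = negative-selection rank below a threshold (default 300,
the convention for a full-size cistrome library; `"auto"` scales it to 5%
of the site count for smaller synthetic libraries). Nonessential =
permutation p > 0.5 and |site LFC| < 0.1 — clearly unselected sites. The
larger class is downsampled (seeded, uniform) until the class ratio lies in
[0.85, 1.1].

The classifier is an SVM (RBF kernel on standardised features; the kernel
is configurable) whose decision scores — not probabilities — rank sites.
Feature subsets are searched by a genetic algorithm: a population of
subsets (default 24) evolves for a fixed number of generations (default
25); each generation keeps an elite fraction and fills the rest with
children that add, remove, or swap one feature of a parent sampled with
rank-proportional probability. Fitness is AUROC on a fixed, seeded 70/30
train/validation split held out from fitness evaluation; the best subset
ever seen is returned with a non-decreasing best-so-far trace. Population
size, iteration count, and the split are implementation defaults — no
canonical values exist for this procedure.

Evaluation uses stratified 5-fold cross-validation with ROC/PR curves
assembled from pooled out-of-fold decision scores and trapezoidal areas;
single-feature baselines rank sites by the raw feature value
(orientation-free, `max(a, 1−a)`). Error analysis thresholds predicted-
essential at the score quantile matching the labeled prevalence and
profiles TP/FP/TN/FN feature medians with FP-vs-TN and FN-vs-TP rank tests.

## SNP enrichment

Each trait-associated variant (1-based input positions, converted
internally) is assigned an enhancer by a fallback hierarchy: overlapping
DNase peak, else overlapping TF peak, else a 150-bp window centered on the
SNP; within a tier the peak whose midpoint is nearest wins, making
assignments independent of peak order. Per trait, a chi-square test
(continuity correction off by default, on by flag) evaluates the 2x2 of
trait SNPs in/out of the essential-enhancer set against the background
enhancer composition, switching to Fisher's exact test when an expected
cell drops below 1; BH adjustment runs across traits and the significance
line is FDR < 20% with fold enrichment above 1. Fold enrichment is the
in-essential SNP rate over the essential fraction of the background. The
background defaults to all enhancers of the relevant factor class. A
rank-sum comparison contrasts the predicted scores of trait-bearing
enhancers with all scored enhancers.

## Reference benchmarks and problem sizes

The standard benchmarks (in `cistrome_ess.benchmarks`, also run by
`scripts/acceptance.py` and the acceptance tests) use desk-scale problem
sizes chosen to finish in seconds while keeping the statistics well
powered: a 1,000-site screen with 16 guides/site and 5% essential sites for
beta recovery; the 2,000-guide-neutral-arm null screen for calibration; a
confounder-isolation screen (null truth, −0.1/extra copy) for the CNV
check; 600-site screens over 10 seeds for feature-ranking order recovery;
a 2,000-site screen for the prediction benchmark; and 800-site screens with
500-SNP traits at 3x and 1x for enrichment recovery. The benchmark effect
shifts (DNase 1.4, H3K27ac 0.8, TF binding 0.2 on the log scale) keep the
qualitative ordering — open chromatin strongest, enhancer mark
intermediate, raw TF binding weakly informative — with pairwise gaps sized
so a rank test on a ~30-site essential group can resolve the order. For
ranking benchmarks the truth is driven by the latent essential flag rather
than the feature values themselves, so group differences reflect only the
injected shifts: feature-driven selection would saturate the rank tests and
leave the ordering undefined. For the enrichment 2x2 the essential set uses
the stringent FDR < 0.05 screen hits — a high-precision set; the permissive
FDR < 0.25 set deliberately admits borderline sites and dilutes fold
estimates.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open throughout (BED convention); SNP input
positions are 1-based. Tie-breaks are deterministic everywhere (guide
selection: distance, then coordinate, then strand; nearest gene: lower
coordinate). Permutation p-values use the +1 correction and never return 0.
Sites with zero guides, samples with all-zero counts, empty essential sets,
classes with fewer than two members, and guide classes without a truth
mapping raise errors naming the failing rule. An all-diploid screen makes
the CNV adjustment the identity rather than an error. Constant features
rank last with p = 1 and an undefined direction.

## Known limitations

The trimmed-mean beta ignores guide-efficiency weights and shares no
information across conditions, unlike a joint MLE. The control-based null
assumes control guides are exchangeable with site guides under no
selection. The linear CNV model removes monotone trends only. GA search is
stochastic and returns a good, not provably optimal, subset. Simulated
screens are far smaller than real cistrome libraries, and all recovery
statements are with respect to the simulator's generative assumptions.
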