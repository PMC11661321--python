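# Methods

## The model

At one GWAS locus with $M$ variants, let $\hat a$ be the vector of GWAS
z-scores, $R$ the LD correlation matrix, and $\hat B = [\hat\beta_{11},
\dots, \hat\beta_{JT}]$ an $M \times JT$ matrix of cis-regulatory (xQTL)
effects of $J$ genes measured in $T$ tissues.  TGVIS models

$$\hat a \sim \mathcal N\big(R(\hat B\theta + \gamma + \upsilon),\
\sigma_\alpha^2 R\big), \qquad \upsilon \sim \mathcal N(0,
\sigma_\upsilon^2 I),$$

where $\theta$ holds sparse causal effects of gene–tissue pairs, $\gamma$
sparse direct (horizontally pleiotropic) variant effects, and $\upsilon$
dense infinitesimal effects capturing local polygenicity.  The three
sparsity assumptions are the usual fine-mapping ones: few causal xQTLs per
pair, few causal pairs, few direct variants with relatively large effects.
Internally everything is handled on the z-score scale; reported effects are
rescaled to the standardized-trait (per-SD) scale by $1/\sqrt{n}$.

## Estimation

**Stage 1 — cis effects.**  Each pair's xQTL z-scores are fine-mapped by a
sum-of-single-effects (SuSiE) fit with $L = 3$.  A variant's posterior-mean
effect enters the pair's column of $\hat B$ iff it lies in a 95% credible
set with PIP > 0.25, or its individual PIP exceeds 0.5.  Diluted sets
(many weakly correlated members, all PIPs small) are thereby discarded.
Pairs are pre-screened by the burden association $z = \hat\beta'\hat a /
\sqrt{\hat\beta'R\hat\beta}$ at two-sided $P \le 0.05$.

**Stage 2 — joint selection.**  The stacked design holds the $K$ retained
normalized pair scores followed by the $M$ variants; its z-vector and
correlation matrix follow from $R$ and $\hat B$ by exact algebra.  SuSiE on
this design (our own implementation: iterative Bayesian stepwise selection,
per-effect slab variances estimated by bounded 1-D likelihood maximization
with a null check, purity-filtered 95% credible sets) selects $(\theta,
\gamma)$.  Coordinates outside reported credible sets are exactly zero.

**Infinitesimal component.**  Given $(\theta, \gamma)$, the BLUPs solve the
penalized quasi-likelihood ridge system $\upsilon = (R + \lambda
I)^{-1}(\hat a - \eta)$ with $\eta = R(\hat B\theta + \gamma)$ and
$\lambda = 1/\sigma_\upsilon^2$ (the variance ratio is profiled with
$\sigma_\alpha^2$ fixed at 1, avoiding the non-identifiability of the two
scales), and the variance follows the REML fixed point
$\sigma_\upsilon^2 = \|\upsilon\|^2/M + \mathrm{tr}[(R + \lambda
I)^{-1}]/M$.  Two numerical choices matter here:

* *Fixed-point seeding.*  The REML step size is proportional to
  $\sigma_\upsilon^2$ itself, so iterating from a near-zero start crawls
  (thousands of iterations to reach an $O(1)$ fixed point).  The inner
  block is therefore seeded at the method-of-moments value implied by the
  current residual, $E\|\hat a - \eta\|^2 = M + \sigma_\upsilon^2\,
  \mathrm{tr}(R^2)$, and the fixed point is then iterated to convergence in
  the eigenbasis of $R$ (cheap: one $O(M)$ pass per step).
* *Upsilon-first initialization.*  The alternation's fixed point depends on
  who claims a signal first.  Starting from selection lets the first SuSiE
  pass claim every marginal signal; the ridge then never captures the
  small effects it exists for.  Starting from a full-strength ridge
  swallows moderate genuine signals.  The implementation initializes the
  ridge at a moderate strength ($\sigma_\upsilon^2 = 0.5$ on the z scale,
  about one-third absorption for unit eigenvalues): small effects sink
  into the polygenic background, genuine signals still stand out and are
  then progressively freed from the BLUPs as the alternation proceeds and
  the variance is re-estimated.

**Gating.**  Whether the infinitesimal component is used at all is decided
once by the variance-component score test of $H_0: \sigma_\upsilon^2 = 0$
(Satterthwaite-type): with $A$ the selected columns $[R\hat B_{\mathcal
M_\theta}, R_{\mathcal M_\gamma}]$ and $P = R^{-1} - R^{-1}A(A'R^{-1}A)^{-1}
A'R^{-1}$,

$$u = \tfrac12\|\hat a - A\vartheta\|^2,\quad e = \tfrac12\mathrm{tr}(PR^2),
\quad h = \tfrac12\mathrm{tr}(PR^2PR^2),$$

and under $H_0$, $u \sim \kappa\chi^2_v$ with $\kappa = h/2e$, $v =
2e^2/h$.  Acceptance forces $\upsilon = 0$.  The statistic is implemented
exactly as printed ($u$ unweighted by $R^{-1}$); a config switch provides
the $R^{-1}$-weighted variant for sensitivity analysis.  $\vartheta$ uses
the SuSiE posterior means of the selected coordinates.  Empirical null
calibration (1000 draws, level 0.05) is part of the test suite.

**Choosing L.**  The number of single effects is selected on the grid
$\{2,\dots,8\}$ by the summary-data criterion $\mathrm{BIC} =
\log\hat\sigma_\alpha^2 + (\log M/M)\,\mathrm{df}$, where
$\hat\sigma_\alpha^2 = (\hat a - R(\hat B\theta + \gamma + \upsilon))'
R^{-1}(\cdot)/M$ and df counts one degree per reported credible set (a
multi-member set represents a single underlying effect; a per-member count
is available by config).  The grid is scanned twice: first without the
infinitesimal component (this pass also feeds the score test), then — if
the test rejects — with the component active at the variance estimated at
the first pass's minimizer.  The variance is held *fixed* across the second
scan because re-estimating it at every L lets the BLUPs absorb arbitrarily
much of whatever the sparse part misses; $\hat\sigma_\alpha^2$ then
collapses at every L and the criterion would degenerate to the smallest
model.  With the ridge absorbing small effects, the second scan typically
settles on a sparser model, which is the intended behavior of the
component.

## Pratt index

For standardized variables the Pratt index of variable $j$ is $V_j =
\beta_j\,\mathrm{cor}(X_j, y)$; it is additive and sums to the model
$R^2$.  Per pair, $\hat V_{jt} = \hat\theta_{jt}\hat\beta_{jt}'\hat a /
(\hat a'R^{-1}\hat a)$, equal to the product of the standardized effect and
the marginal correlation (the printed transformation of $\hat\theta$ lacks
the square roots that make this identity hold; the implementation uses the
square-root form, and the two-route identity is asserted to 1e-12 in the
tests).  A credible set's CS-Pratt is the sum over members; the component
aggregates decorrelate the linear predictors through $R^{1/2}$ (eigenvalue
floor 1e-8).  Causal prioritization keeps sets with CS-Pratt strictly
above 0.15; a data-driven threshold via 1-D K-means (minimum of the
higher-centroid cluster) is provided but not used by default.  The
infinitesimal component has no credible set and is reported only at
component level.  Pratt values are comparable only within a locus.

## Baselines

The cTWAS-style baseline is the identical two-stage selection with the
infinitesimal component forced off (single locus, no genome-wide EM
priors; fixed $L = 5$ by default).  The TGFM-style baseline propagates
stage-1 uncertainty: 100 outer iterations each average 25 posterior draws
of every retained pair's cis-effects, refit the stacked selection, and
record PIPs; empirical PIPs are per-iteration means, the point fit uses
the mean resampled cis-effect matrix, and degenerate resampling (zero
posterior variance, one iteration) reproduces the cTWAS-style fit exactly.

## The synthetic-data generator

A locus is 20 genes x 5 tissues (100 pairs) over $M = 400$ variants in 20
LD blocks of 20 (within-block AR(1), $\rho = 0.6$; zero between blocks —
a standard stand-in for the unavailable generation details, configurable).
Per gene, 1–4 causal xQTL positions are drawn, partially (probability 0.3)
from a pool shared between genes; each tissue inherits the gene's
positions but with probability 0.25 shifts one to an LD neighbor (+/-1–2
variants), and effect sizes are correlated 0.8 across tissues.  Each
pair's column is normalized to a cis heritability of expression of 0.3
(typical of well-powered fine-mapped eGenes).  Tissues sharing *every*
causal variant would make sibling pairs of a one-xQTL gene exactly
collinear — statistically indistinguishable by any method — which is why
the position shift exists; fine-mapping studies find only about half of
cross-tissue eQTL pairs share their causal variant.

Pairs 1 and 100 are trait-causal with $\theta = +1, -1$.  Scenario
`direct` adds two direct causal variants (distinct blocks, off every
pair's xQTL positions); `infinitesimal` adds $\upsilon_m \sim \mathcal
N(0, \sigma_\upsilon^2)$; `both` adds both.  Active components are scaled
to equal shares of the locus signal (50/50 or 33/33/33).  Summary
statistics are drawn at the summary level — $\hat a_z \sim \mathcal
N(\sqrt{n_{\rm trait}}\,R(B\theta + \gamma + \upsilon)/s_y,\ R)$ and
$\hat b_z \sim \mathcal N(\sqrt{n_{\rm eQTL}}\,R\beta,\ R)$ — with the
trait SD $s_y$ set so the locus explains `local_h2` of trait variance.
Defaults: $n_{\rm trait} = 500{,}000$ ("0.5M" read as 500,000), $n_{\rm
eQTL} \in \{100, 200, 400, 800\}$ with 200 the benchmark value, and
`local_h2` = 0.0025 — a typical genome-wide-significant cardiometabolic
locus (top burden |z| around 15–25); this scale also determines how hard
infinitesimal effects are to recover (the per-variant signal SD on the z
scale is $\sqrt{n\,h^2_{\rm local}\,s/M}$ for share $s$), matching the
reported difficulty of that task.  What the generator does *not* emulate:
real LD (long-range, rank-deficient reference panels), allele-frequency
spectra and strand issues, sample overlap between GWAS and xQTL studies,
multi-ancestry structure, and sQTL-vs-eQTL feature structure.  Passing
benchmarks therefore demonstrate correct behavior under the generating
model, not performance on real cohorts.

## Evaluation conventions

One credible set is one discovery; its members are statistically tied
representations of a single signal (often exactly tied, e.g. sibling
tissues sharing one xQTL, or a one-xQTL pair and its variant twin).  A
replicate is a true negative when every pair-containing set contains a
causal pair, a true positive when both causal pairs are inside reported
sets; a set containing only variants counts as one direct-variant call.
$\theta$-MSE is computed over all 100 pairs on the generating $\pm 1$
scale (estimates rescaled by $s_y$); a method reporting $\upsilon \equiv 0$
scores an infinitesimal-recovery correlation of 0.

## Problem sizes

The benchmark behind `scripts/acceptance.py` runs 48 replicates per
scenario (four scenarios at $n_{\rm eQTL} = 200$) with all three methods
and the TGFM-style baseline at its full 25 x 100 resampling depth; the
test suite's end-to-end fixture uses 56 replicates per scenario with 50
outer resampling iterations.  Monte-Carlo standard errors at these sizes
are a few hundredths on the rate metrics.

## Numerical details and edge cases

LD is regularized as $(1-\varepsilon)R + \varepsilon I$, $\varepsilon =
10^{-3}$, before any solve; all inverses, square roots and ridge solves go
through one eigendecomposition per locus (eigenvalue floor 1e-8).  SuSiE
convergence is declared when the mean-field objective changes by less than
1e-6 (at most 500 inner iterations; 150 in pipeline use); the outer
alternation stops when the max-norm parameter change is below 1e-5
relative to $1 + \max|{\rm parameter}|$ (absolute tolerances are
meaningless on the z scale), at most 30 outer iterations.  Effects whose
estimated slab variance falls below 1e-9 are pruned and report no set.
Credible-set membership sorts by descending posterior weight with index as
tie-break; duplicate member sets are reported once; purity below 0.1
discards a set.  Strand-ambiguous (A/T, C/G) variants are dropped by
default at harmonization, as are multi-allelic IDs; zero-norm cis-effect
columns are excluded; an empty stacked design falls back to
variants-only selection.
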