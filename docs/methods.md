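# Methods

This note documents the statistical machinery, the defaults and the
numerical choices the package makes, and what its synthetic data can and
cannot show.

## Independent contrasts and ancestral states

The contrasts recursion follows the standard postorder algorithm for a
continuous trait on a rooted bifurcating tree.  For daughters i, j with
values x_i, x_j and branch lengths v_i, v_j (already lengthened by any
collapsed descendants):

* raw contrast x_i − x_j, standardized by √(v_i + v_j);
* nodal value (x_i/v_i + x_j/v_j)/(1/v_i + 1/v_j);
* branch to the parent lengthened by v_i·v_j/(v_i + v_j).

Under Brownian motion with rate σ² the standardized contrasts are iid
N(0, σ²); the rate is estimated REML-style as the mean squared
standardized contrast, Σc²/(n−1).  Polytomies are resolved at parse time
into zero-length bifurcations (children in input order, folded from the
left) — a deterministic choice that leaves the tip covariance matrix
unchanged, so contrasts, likelihoods and GLS means are unaffected by
the arbitrary resolution order.  A sister pair whose branch lengths sum
to zero has no defined contrast and is an error rather than silently
dropped.

Ancestral state of node k: the tree is re-rooted at k (tip-to-tip path
lengths preserved; the superseded root is suppressed) and the recursion
is re-run; the root value of that run is the GLS estimate of the state
at k, with variance factor v_root = 1/Σ(1/v_child) over the new root's
daughters.  SE = √(σ̂²·v_root), with σ̂² taken from the original rooting
so all nodes share one rate estimate.  Node changes are classified
against the parental interval (estimate ± SE): strictly outside is
significant, the direction is the sign of the difference, and exact
equality is "equal" and never significant.  Tip values enter as point
measurements; their own sampling errors are not propagated.

The standardization diagnostic is an OLS regression of |standardized
contrast| on its SD; a two-sided p < 0.05 flags inadequate
standardization.  Degenerate inputs (identical SDs, or |contrasts| flat)
pass by construction, as there is no estimable trend.

## Brownian models and Pagel transforms

Tip values are multivariate normal with covariance σ²C, C[i,j] the
shared root-to-MRCA path length.  Transforms are applied in the fixed
order κ → δ → λ: κ exponentiates each branch length before C is rebuilt
(so 0⁰ = 1 gives the unit-branch "punctuational" limit at κ=0); δ is an
element-wise power on C; λ scales the off-diagonal only.  δ is
implemented element-wise on the covariance (the depth-matrix
convention); the alternative per-node depth rescaling differs only in
how it handles non-ultrametric depth asymmetry, and the element-wise
form is the one documented for the covariance representation this
package uses.

The mean is α (random walk, "Model A") or α + β·d_i ("Model B"), with
d_i the transformed root-to-tip path length.  α (and β) are profiled by
GLS through the Cholesky factor of C, σ² analytically (denominator n by
ML; an n−p REML variant is exposed for concordance with the contrast
rate).  The remaining free transform parameters are maximised by
bounded L-BFGS-B from a fixed 3-point grid per parameter (κ, δ:
{0.5, 1, 2}; λ: {0.2, 0.6, 1}), so fits are deterministic without a
seed.  Bounds: κ ∈ [0, 3], λ ∈ [0, 1], δ ∈ (0, 3].

Numerical choices: if the Cholesky fails, one ridge of
1e-10·trace(C)/n is added; a second failure is an error advising
zero-branch collapse.  Constant traits drive σ̂² to the zero boundary
and are returned flagged degenerate rather than as a spurious infinite
likelihood.  On an ultrametric tree all d_i are equal and β is
confounded with α; Model B detects the constant regressor and refuses.

The likelihood has a second, independent implementation through the
contrasts factorisation (n−1 contrast densities times the root-estimate
density, unit Jacobian), used as an oracle against the dense
multivariate-normal route in the tests.

## MCMC and Bayes factors

The sampler is Metropolis–Hastings with single-parameter sliding-window
proposals under independent uniform priors: σ² ~ U(0, 100·var(x)),
α ~ U(range(x) ± 3 SD), β ~ U(±10·SD per unit mean depth), λ ~ U(0,1),
κ, δ ~ U(0,3); all overridable, and zero-width bounds pin a parameter.
With probability 0.1 per generation the chain instead proposes a
uniformly drawn tree from the supplied tree set, accepted by likelihood
ratio, so inference averages over phylogenetic uncertainty.  Proposal
widths are tuned toward 20–40% acceptance during burn-in only, then
frozen to preserve detailed balance.  Covariance Cholesky factors are
cached on (tree, κ, δ, λ), so chains that only move σ², α or β never
refactorise.

Marginal likelihoods use the harmonic mean of retained likelihoods,
computed in log space (−logsumexp(−ℓ) + log N).  The estimator is
retained because it is the field-standard output the analysis emulates,
with its known defect documented: it is an upper-biased, high-variance
estimator whose noise is dominated by the lowest-likelihood samples
visited, so short chains can produce spurious Bayes-factor spikes in
either direction.  A stepping-stone estimator (β-quantile ladder,
per-rung tempered chains) is provided as an opt-in cross-check.  Bayes
factors are 2·(Δ log marginal); evidence categories are >2 positive,
>5 strong, >10 very strong, assessed on the magnitude.

The model battery runs, per trait: a null random-walk chain with all
transforms pinned at 1, one chain per transform left free, optional
chains with λ or κ pinned at 0, and a directional chain, and reports
each free-vs-pinned comparison plus directional-vs-random-walk.

Chain-length defaults are a documented 100× scale-down (10⁶
generations, 10⁵ burn-in, thin 100) of the 10⁸/10⁷ schedule the
emulated analysis used.  The packaged calibration runs (acceptance test
and script) use 2×10⁴ generations with 4×10³ burn-in and thinning 10
per chain on 100-tip trees, which keeps a ten-replicate battery to a
few minutes.  The harmonic-mean noise occasionally exceeds the
"positive evidence" threshold on null data at any desktop schedule
(spot checks at 6×10⁴ generations show the same occasional spikes):
this is a property of the estimator, not of the data, and is why
borderline Bayes factors should not be over-read.

## Correlations and group statistics

Raw correlations are ordinary Pearson with the exact t-based p
(t = r√(n−2)/√(1−r²)).  Contrast correlations are constrained through
the origin — contrast signs are arbitrary, so no intercept is estimable
— with r = Σc_x c_y / √(Σc_x² Σc_y²) and t on n−1 df; pairs are
oriented so the first trait's contrast is non-negative, which fixes the
reported sign without affecting any through-origin statistic.  Both
modes are reported for sensitivity.  Group means are compared by
Welch's t; variances by a two-sided F-ratio test (a "t-test on
variances" is not a standard procedure; the report labels the
substitution).  Summaries use sample SDs (n−1); the pooled "total" row
covers the two ingroup subgenera and excludes the outgroup, which
reproduces the packaged table's printed pooled mean.

The packaged table's printed within-*Passiflora* correlation is
reproduced only when the outgroup species is pooled with the subgenus
(r = 0.630 vs 0.617 for the 36 labelled species); the report carries
both values.

## Synthetic data

`simulate_tree` draws Yule (pure-birth) trees: inter-event times are
exponential with rate k·birth while k lineages are extant, and one
trailing inter-event segment is added so the youngest cherries keep
positive branch lengths; the expected root-to-tip depth is
Σ_{k=2..n} 1/(k·birth).  Pure-birth time trees are ultrametric; where a
molecular tree is being emulated (the two-clade preset, directional
fits, the battery calibrations) branch lengths receive multiplicative
lognormal rate jitter (sd 0.3 on the log scale), which breaks
ultrametricity the way substitution-rate variation does.

`simulate_bm` runs the preorder Gaussian walk (child = parent + β·b +
N(0, σ²b)) on κ-transformed branches; for λ or δ the tip vector is
drawn directly from the transformed covariance, which is the same
distribution.  Correlated two-trait simulation applies the Cholesky
factor of the 2×2 per-unit-time trait covariance to shared increments.

The `make_passiflora_like` preset fixes the study conditions: sister
clades of 36 and 13 tips (clade height 0.75, stems 0.25, outgroup at
depth 1.2, arbitrary time units), clade root states at the packaged
clade means (GS 1.311/0.413 pg; FD 7.28/2.92 cm), per-clade rates set
from the target tip SDs via rate = SD²/(height·0.65) — the 0.65 being
the approximate fraction of root-to-tip Brownian variance that spreads
tips around a Yule clade's mean, the rest being shared ancestry — and
cross-trait correlation 0.6.  Trait values are floored at 0.05 pg /
0.1 cm to respect positivity (rarely binding at these rates).  The
"posterior" tree set is 100 branch-length-jittered copies (lognormal,
sd 0.1).  What this does not emulate: the real group's topology, its
non-Brownian features (bounded genome sizes, possible punctuational
flower-size change), measurement error in the traits, and topological
(rather than branch-length) uncertainty in the tree set — so passing
calibrations demonstrate internal consistency of the machinery, not
properties of the real data.

## Known limitations

* The harmonic-mean marginal likelihood is noisy at desktop chain
  lengths; treat borderline Bayes factors (|BF| near 2) as
  inconclusive, or use the stepping-stone cross-check.
* Ancestral-state SEs condition on the tree and the point rate
  estimate; they understate uncertainty when either is poorly known.
* One trait at a time: no multivariate contrasts or correlated-trait
  likelihood models (contrast correlation covers the bivariate
  question).
* Trees must be rooted with branch lengths; unrooted-tree workflows are
  out of scope.
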