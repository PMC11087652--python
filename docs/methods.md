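# Methods

## The model of the data

The unit of analysis is inter-subject correlation (ISC): for subjects
*i*, *j* and voxel *v*, the Pearson correlation of their BOLD time
series at that voxel.  ISC is kept on the raw *r* scale throughout —
the change analysis subtracts before-conversation ISC from
after-conversation ISC, so any monotone transform of *r* would change
the meaning of the differences.  A `fisher_z` flag exists on the ISC
constructors for sensitivity analyses only; no default analysis uses
it.

Voxels with zero temporal variance in any subject produce NaN (an
explicit undefined marker, not 0 and not an exception) and are dropped
per voxel from regressions and summaries.  Real pipelines meet such
voxels at mask edges; the synthetic generator never produces them
except in deliberately constructed tests.

## Synthetic cohorts

The generator produces the statistical structure the analyses assume,
not realistic physiology.  Each subject's series at each voxel is a
variance-partitioned mixture of independent unit-variance sources:

    x[s,v,t] = sqrt(a) g[v,t] + sqrt(b_ses) h[grp(s),v,t]
             + sqrt(1 - a - b_ses) eps[s,v,t]

* `a` (`a_shared`) — cohort-wide stimulus-driven signal.  Default 0.15,
  a typical magnitude for engaging naturalistic stimuli in sensory
  cortex.
* `b_ses` (`b_group_pre`, `b_group_post`) — group-specific signal,
  carried only by voxels in the affected mask.  Raising `b` from the
  pre to the post session plants a convergence effect of exactly
  `b_post - b_pre` in expected within-group ISC change.
* `g` and `h` belong to the *clip* and are shared across the two
  viewings; only the noise is redrawn per session.  Consequently the
  cross-session ISC between two subjects is `a + sqrt(b_pre b_post)`
  within groups at affected voxels and `a` otherwise, and the directed
  influence statistic is centred on zero unless imitation is injected.

Expected ISC values are exact closed forms because all components are
unit-variance and independent: within-group ISC at an affected voxel
is `a + b`, all other pairs/voxels give `a`.  Directed imitation is
injected per ordered pair by replacing the alter's post series with
`sqrt(w) ego_pre + sqrt(1 - w) noise`, giving expected
`ISC(ego_pre, alter_post) = sqrt(w)`.

Signals are temporally white by default so that the closed forms are
exact and permutation nulls are clean; an `ar1` coefficient exists
because real BOLD is autocorrelated, with default 0 (enabling it
changes the effective degrees of freedom of windowed correlations but
not the expected ISC values).

The affected mask is a contiguous axis-aligned block at the grid
origin (default ~`affected_fraction` of the volume, or an explicit
`affected_block`) so cluster-level inference has spatial structure to
find; the voxel grid is 3-D with row-major flattening.

Surveys use 12 items per clip on a 1-7 integer scale (a plausible
Likert layout; nothing downstream depends on the particular choice).
Post-conversation answers move toward the conversation-group mean by a
factor `pull` and are re-rounded; `pull = 1` collapses a group onto
identical answers, `pull = 0` is the no-conversation null.  Turn
tables draw speakers with weights exponential in perceived status
(`status_talkativeness`, default 0.8), so status inequality produces
turn-taking inequality measurable by the Gini coefficient; a planted
word stem can be emitted at a rate proportional to speaker status for
word-regression recovery tests.

Cohort-scale defaults mirror the target design: 9 conversation groups
of 3-6 members (40 conversers) plus 9 no-conversation controls, 5
clips, two sessions.  The default grid (8x8x8, 200 TRs) is a
desk-scale stand-in for a brain; all statistics scale with voxel count
only linearly, so nothing in the inference logic depends on the size.

What the generator does *not* emulate: hemodynamic convolution,
spatial autocorrelation of noise, motion and physiological artifacts,
anatomical variability, non-stationary engagement.  Passing tests
therefore certify the statistical machinery (estimator identities,
calibration, recovery), not robustness to fMRI artifacts, which a real
preprocessing pipeline must handle upstream.

## Change regression

Per voxel, the change matrix (post ISC minus pre ISC) is vectorized
over the strict lower triangle of the pair matrix — unordered pair
analyses never duplicate cells — concatenated across clips, and fit by
OLS on pair predictors: an all-1s intercept, plus either one indicator
per conversation group or a single any-group indicator.  Between-group
and control pairs always remain in the rows; the intercept absorbs
change common to all pairs (e.g. from re-watching), so group betas are
interpreted relative to it.  A group needs at least two members to
form a column, otherwise the design is rejected by name.  Rank
deficiency is rejected with the collinear columns named.

The novel-clip variant uses the post-session ISC matrix itself as the
target with the same predictors, testing whether group alignment
generalizes to stimuli never discussed.

## Subject-wise permutation inference

The null is built by relabeling subjects: one permutation per draw,
applied identically to the rows and columns of every clip's target
matrix while the design is held fixed.  The same relabeling is reused
across concatenated clips — permuting independently per clip would
break subject exchangeability in the concatenated model, since the
same subjects underlie every clip.  Two-tailed p-values use add-one
smoothing, `p = (1 + #{|b_perm| >= |b_obs|}) / (1 + n_perm)`, which
avoids impossible p = 0 at finite n_perm and is the natural estimator
when the identity permutation is included; exhaustive enumeration
(all N! relabelings, small N) uses the raw proportion because the
identity is already among the draws.  The raw-proportion rule for
sampled draws is available behind `smoothing=False`.

Default draws: 2000.  Calibration on null cohorts is the headline
guarantee: the type-I error at alpha = 0.05 is checked to land in
[0.03, 0.07] over 500 independent voxels, and the sampled p-values are
checked against the exhaustive 720-permutation enumeration at N = 6.

## Cluster-extent correction

Suprathreshold voxels (two-tailed permutation p below the
cluster-forming threshold, default 0.01) are grouped into connected
components per predictor and per sign — positive and negative effects
are corrected separately, since a sign-mixed cluster has no coherent
interpretation.  Connectivity is face adjacency (6) by default,
configurable to 18/26.  A component survives if it has at least
`min_size` voxels (default 32).  Alternatively a permutation
max-cluster null can be supplied: each permuted beta map is converted
to voxelwise pseudo-p values against the pooled per-voxel null,
thresholded and labeled identically, and the 95th percentile of max
cluster sizes becomes the survival threshold.  This replaces
ACF-model-based cluster simulation with a null derived from the same
subject-wise permutation scheme as the voxel-level inference, and is
self-consistent with it.  Cluster tables report size, member voxel
indices, and the mean, peak and bootstrap 95% CI of member betas.

## Neural influence

For ordered pair (ego e, alter a):
`influence_v(e,a) = ISC_v(e_pre, a_post) - ISC_v(e_pre, a_pre)` — the
initial-position matrix subtracted from the final-position matrix,
directly interpretable as how much more similar the alter became to
the ego's initial series.  Both triangles are used (each subject
appears as ego and as alter); the diagonal is undefined.  Vectorization
order is (clip, ego-major, alter-minor) and is stable.

Centrality regressions put the ego's or the alter's z-scored
centrality where the group indicators had 1s, over same-group ordered
pairs only.  Z-scoring is over the study-participant subsample by
default (the analysis population), with a flag to use the full cohort
network.  Two composite models are fitted: PCA centrality alone, and
eigenvector + brokerage jointly (their unique contributions).  An
intercept over ordered pairs is included — the influence baseline is
not constrained to zero, and omitting the intercept would push any
common offset into the centrality betas.

## Network centrality

Friendship nominations give a simple digraph.  Both metrics are
computed on the union-symmetrized graph by default: directed
eigenvector centrality is ill-behaved for sink nodes of nomination
graphs, and Burt's proportional strengths conventionally pool mutual
ties; a `directed` flag keeps the digraph treatment (pooled in- and
out-strengths for constraint, right eigenvector for centrality).
Eigenvector scores are max-normalized to 1.  Constraint follows Burt's
double sum over proportional tie strengths; brokerage is
`constraint^-0.5`, strictly decreasing in constraint; isolates are
undefined (NaN).  The PCA composite z-scores both metrics, projects on
the first principal component, and orients the sign so the eigenvector
loading is positive; the node set the PCA is fitted on is
caller-visible because cohort networks and participant subsamples give
different standardizations.

## Behavioral layer

Survey distance is city-block over the concatenated answer vector.
The session x comparison-type model
(`distance ~ before + within + before:within`, random intercepts per
pair) is delegated to a standard mixed-model routine; the bespoke part
is the permutation wrapper: the dependent variable is shuffled across
rows and the marginal R^2 (fixed-effect variance over fixed + random +
residual) recomputed, at least 200 draws by default (2000 for final
runs).  If the mixed fit is degenerate (zero residual variance happens
at pull = 1), the fit falls back to OLS with a zero random-intercept
variance, which leaves the fixed effects and marginal R^2 defined.

Survey influence mirrors neural influence on the city-block metric:
`d(ego_pre, alter_pre) - d(ego_pre, alter_post)`.  This is a design
choice for the directed behavioral statistic, chosen for symmetry with
the neural definition.

The Gini coefficient uses the population form
`G = sum_ij |x_i - x_j| / (2 n^2 mean)` with no small-sample
correction (G([0,1]) = 0.5), computed via the sorted-rank identity and
cross-checked against the literal double sum.

Word-stem filtering applies, in order: fold stems used fewer than 5
times overall into a RAREWORD placeholder, then keep stems used by at
least 10 speakers and in at least 3 clips (breadth filters exclude
speaker- and clip-specific vocabulary).  Word-level models are single
OLS regressions of the z-scored speaker covariate (PCA centrality or
perceived status) on all surviving stem counts; permutation p-values
shuffle the covariate across speakers, not turns, because the
covariate is constant within speaker.

The pair-structured correlation test (e.g. whole-brain alignment vs
survey convergence) permutes subject labels and re-reads one variable
at the relabeled cells, respecting the dependence of pairs sharing a
subject.

## Numerical choices and degenerate inputs

* Correlations are clipped to [-1, 1] against floating-point overshoot.
* Rolling windows map to the TR at `start + window // 2` (leftward
  tie-break for even windows); windows below 3 TRs are rejected as
  degenerate for correlation.
* OLS is solved by `lstsq`; oracle tests pin it to the normal-equation
  solution at 1e-8 on dozens of random instances.
* Bootstrap CIs in cluster tables use 1000 resamples of member voxels,
  seeded.
* All generators and analyses are pure functions of their inputs and
  seeds; the pipeline embeds the config hash and seed in every output
  and is byte-identical across reruns.

## Problem sizes

Validation studies run at sizes chosen so every check completes in
minutes on one CPU while keeping the estimators in their asymptotic
regime: null calibration at 20 subjects / 500 voxels / T = 200 /
1000 draws; recovery at 14 subjects / 216 voxels (64 planted) /
T = 400 over 100 cohorts; influence at T = 400.  The package-default
cohort (49 subjects, 5 clips, 512 voxels) runs end to end in the
analysis drivers.

## Known limitations

* No hemodynamic model, spatial noise correlation, or artifact model
  (see above); no leave-one-out ISC variant (the analyses are strictly
  pairwise by design).
* The permutation max-cluster null recomputes pseudo-p values from the
  pooled permuted betas; with very small `n_perm` its threshold is
  coarse.
* Mixed-effects models beyond random intercepts (nested raters,
  crossed speaker/coder designs) are out of scope; the fitting
  contract accepts only the random-intercept grouping the analyses
  need.
* Whole-brain alignment/influence sums positive values only, so they
  are sensitive to voxel count; compare them only within a fixed grid.
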