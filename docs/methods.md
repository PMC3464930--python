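# Methods

## Model

`drem2` models a time-series expression experiment as a tree-structured
input-output hidden Markov model (IOHMM).  The tree has one level per time
point; a node (state) at time *t* emits a univariate Gaussian
N(μ, σ²) over the log2 expression ratio at *t*, and a root-to-leaf path is a
candidate trajectory shape.  Most nodes have a single child; a *split node*
has 2–3 children and marks a bifurcation point — a time at which a set of
previously co-expressed genes diverges.

What makes the model an IOHMM rather than a plain tree HMM is the transition
law at splits: the probability that a gene takes child *k* is a multiclass
logistic regression over that gene's TF-binding features,

  P(child k | gene g) = softmax_k( w_k · b(g, t) + w_k0 ),

with child 0 the fixed zero-weight reference class.  The feature vector
b(g, t) holds one binding value per TF for the transition into the
children's time point *t*: either the static grid (classic topology, one
input node for all transitions), a per-time-point grid (fully dynamic), or
a merge in which a TF with a dynamic grid at *t* overrides its static row
(mixed topology).  Binding values are three-state (−1 repressor, 0 none,
+1 activator) or continuous nonnegative evidence such as b = −log10 of a
ChIP peak p-value; the classifier therefore weighs strongly bound targets
more than weakly bound ones.

A gene's likelihood is the sum over all root-to-leaf paths of the product
of emission densities and transition probabilities along the path.  Trees
here are small (≤ 3^(T−1) leaves, in practice a handful), so inference
enumerates paths exactly in one vectorized pass down the tree; no
forward-backward approximation is involved.  Missing observations are
marginalized (their emission term is 0), never imputed.

## TF-expression prior scaling

When enabled, a TF's feature row for the transition into time *t* is
multiplied by

  m(e) = 2·σ(w·e),

where e is the TF's own log2 ratio at *t*, σ the standard logistic function
and w ≥ 0 the *expression scaling weight* (default 1).  m is the unique
form, up to the weight parameterization, that is a logistic function of TF
expression, neutral (×1) at e = 0 and at w = 0, bounded in (0, 2), and
symmetric: up-regulated TFs have their binding prior elevated, repressed
TFs depressed but never zeroed (repressors can still act).  Scaling changes
magnitudes only — sign and sparsity of the binding grid are preserved.

## Fitting

**EM.**  For a fixed tree, the E-step computes exact per-gene posteriors
over leaves; the M-step re-estimates every state's μ and σ² by
posterior-weighted moments (variance floored at 1e-4) and refits every
split's classifier by posterior-weighted, L2-penalized maximum likelihood
(λ‖w‖², default λ = 1, intercepts unpenalized).  The classifier subproblem
is convex and solved by L-BFGS to a gradient norm of ~1e-6, warm-started
from the current weights, so the penalized data log-likelihood is
non-decreasing across iterations (slack 1e-8; verified over 50 seeded runs
in the test suite).  Iteration stops when the gain drops below `em_tol`
(default 1e-3) or after `em_max_iter` (100) iterations.

**Structure search.**  Search starts from the single-path chain (whose EM
fit reduces to per-time-point moments) and greedily grows the tree: every
node below the last time point with out-degree < K_max (default 3, matching
the at-most-ternary splits the method reports) may gain one more child —
binary splits first, then ternary.  A proposal attaches a fresh chain from
the split time to the horizon, initialized at the 0.25 and 0.75 quantiles
of the values of the genes currently routed through the node (both
initializations are tried), refits by EM, and is scored by

  score = penalized log-likelihood − κ · (#free parameters),

with κ = ½·log(n_genes) (BIC).  Free parameters are two per state plus
(d+1) per non-reference child of each split.  We penalize parameters rather
than states alone: a state-count penalty ignores the d+1 classifier
parameters each extra child buys, and on clean single-split data it lets a
cascade of spurious micro-splits through (each worth a few nats, about the
χ²/2 overfitting gain of its unpenalized parameters).  The best improving
proposal is accepted; search stops when none improves the score or when a
new child would capture fewer than `min_path_genes` (default 5) Viterbi
genes.  The whole procedure is deterministic given the configuration: node
order, initialization quantiles and tie-breaks are fixed, so identical
inputs and seed give byte-identical model files.

**Assignment.**  After training, each gene is assigned to the leaf
maximizing its path log-likelihood; ties go to the smallest leaf index.

## Preprocessing

Fixed pipeline order: log2 transform (for ratio input) → replicate collapse
(mean by default, median optional; missing values skipped) → minimum
absolute change filter (a gene is discarded when its max |log2 ratio| over
time is *strictly below* the threshold; default threshold 0, the reference
analysis used 0.5) → optional anchoring, which prepends an all-zero time
point when the first column is not already zero, reflecting the model
assumption that all genes start co-expressed at ratio 0.  Filtering runs
after collapse, so the threshold applies to combined replicate values.
Genes missing more than half their time points are dropped at parse time.

## Annotation statistics

All enrichment tests are one-sided upper-tail hypergeometric tests computed
by exact summation in log space (gammaln + logsumexp).  The split table
reports, per TF and outgoing path, the count of the TF's targets on the
path against (a) the genes entering the split ("conditional on split",
the statistic used to attach TFs to split nodes, display threshold 5e-5)
and (b) all model genes.  A TF "targets" a gene when its effective feature
value is nonzero (an optional threshold supports b ≥ c definitions).  GO
enrichment tests, per path, every term annotating ≥ 1 path gene against the
background of all genes surviving preprocessing (the model's universe, not
the genome), Bonferroni-corrects over the number of tested terms, and calls
terms significant at corrected p < 0.05.  Annotations are propagated to all
ancestors through is_a edges once per gene-term pair; NOT-qualified GAF
rows and obsolete terms are dropped.  TFs attached to a split are flagged
up/down when their own log2 ratio at the split time exceeds ±δ (default
0.5, tied to the min-change default).

## Synthetic data

The generator inverts the model.  The reference scenario plants T = 5 time
points, one binary split at t = 2, mean separation Δμ = 3, emission SD
σ = 0.5, 500 genes and 10 TFs.  Binding is drawn first: the signal TF binds
80% of the genes destined for its path and 10% of the rest; decoy TFs bind
10% of genes; continuous values are Uniform(1, 5).  Each gene's path is
then drawn from the planted softmax (weight 2 on the signal TF, intercept
centred so the marginal is balanced), and its trajectory from the path's
Gaussians.  Binding can be emitted static, fully dynamic (informative grid
at the split transition, decoy grids elsewhere), or mixed (decoy TFs
static, signal TF dynamic).  With TF-expression coupling the signal TF's
own trajectory rises (+1.5) one time point before its split, so prior
scaling can be exercised end to end.  TF rows are appended to the
expression table — regulators are genes too.

What the generator does *not* emulate: array-level noise structure
(probe effects, heteroscedastic intensity-dependent variance),
autocorrelated within-gene noise, overlapping regulatory programs, or
unbalanced path sizes.  Passing recovery tests therefore demonstrates
correctness of inference and search under the model's own assumptions, not
performance on real microarray data.

A companion generator writes toy GO files (OBO 1.2 + GAF 2.2) whose terms
cover random 50–90% subsets of each planted path group plus a 5% leak and a
few background terms, so enrichment results track assignment quality.

## The three-scenario comparison

The comparison protocol trains three variants on the same simulated data —
expression only (no binding features; splits get intercept-only
classifiers, i.e. HMM-based clustering), expression + TF binding, and
expression + TF binding + TF-expression scaling (weight 1) — and compares
the number of GO terms significant after Bonferroni correction.  The study
condition uses a deliberately weak bifurcation (Δμ = 0.5 = 1σ, 400 genes,
coupled TF expression): at one emission SD of separation the expression
data alone frequently cannot justify a split (BIC rejects it), while the
binding features still identify the diverging genes.  The expected ordering
— counts non-decreasing as data layers are added, in the median over 10
seeds — is asserted by the acceptance suite.  At Δμ = 3 all three variants
tie; the weak regime is what makes the comparison informative.

## Numerical choices and problem sizes

- Variance floor 1e-4 on the log2-ratio scale; degenerate states (posterior
  mass < 1e-8) keep their mean and are floored.
- Softmax identifiability: child 0 is always the zero-weight reference.
- Exact-inference and enrichment oracles in the tests are brute-force
  enumerations (path products in plain Python, Fraction-exact draw counting
  for the hypergeometric tail with N ≤ 12).
- Test and acceptance problem sizes — 500-gene recovery runs over 20 seeds,
  50 EM-monotonicity runs at 100 genes, 10 comparison seeds at 400 genes —
  are the package's reference conditions; each recovery run takes a few
  seconds on one core.

## Known limitations

- Greedy, forward-only structure search: splits are never retracted or
  merged, and a wrong early acceptance cannot be undone.
- Per-state variances with a floor; no variance tying across a level.
- Tree topologies only — paths never merge.
- Gene-id matching is exact (case-insensitive, trimmed); no alias
  resolution.
- The classifier is linear in the binding features; interactions between
  TFs are only captured through their joint linear effect.
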