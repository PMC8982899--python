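# Methods

This note documents the models, the numerical choices, and what the
synthetic studies do and do not establish.

## Network inference

Each condition's regulatory network is a dense TF×gene weight matrix W
obtained by a fixed-point message-passing scheme over three z-scored
inputs: the binary regulatory prior W₀, the TF–TF interaction matrix P
(unit diagonal), and a gene–gene co-expression matrix C.  One iteration
computes a *responsibility* R = T(P, W) (is the edge supported by the TF's
interaction neighbourhood?) and an *availability* A = T(W, C) (by the
gene's co-expression neighbourhood?), where T is the continuous Tanimoto
similarity T(x, y) = x·y / √(‖x‖² + ‖y‖² − |x·y|), and relaxes
W ← 0.9·W + 0.1·(R + A)/2.  P and C are simultaneously relaxed toward the
co-regulation structure implied by W; the self-similarity diagonal of those
estimates grows with the vector norms and would feed back explosively, so
it is replaced by the off-diagonal row standard deviation scaled by
n·exp(0.2·iteration), which progressively freezes P and C and drives the
iteration to its fixed point.  Convergence is declared when the mean
absolute difference between W and its message drops below 1e-3 (at most 200
iterations; the last iterate is returned with a warning flag otherwise).
The final W is z-scored over all entries.  No randomness is involved:
identical inputs give bit-identical networks.

**Single profile per condition.**  With one expression column per condition
(the L1000-style situation) a per-condition correlation matrix cannot be
estimated.  The pooled correlation over all conditions is therefore
computed once and *gated* per condition: with response magnitude
u = (|x_cond − x_control| / max)^p the per-gene activation is
a = (1 − λ) + λ·u and C_cond = C_pooled ∘ a aᵀ.  A condition keeps
co-expression between genes in proportion to how strongly it moves both,
so it highlights the co-expressed programs it actually perturbs.  Defaults
λ = 0.8 and p = 2 (sharpening the contrast between strong and weak
responders); λ = 0 recovers a single shared matrix.  The control's gate is
uniform, leaving its co-expression proportional to the pooled matrix.

## Differential modules

The control network is partitioned by maximizing Barber's bipartite
modularity Q = (1/m)·Σ (w_tg − k_t d_g/m)·δ(c_t, c_g); maximization runs a
fast multilevel pass (igraph) for initialization followed by greedy
single-node moves on the bipartite objective, plus a final merge pass that
resolves exact modularity ties toward the coarser partition.  Randomness is
confined to a seeded permutation of the node visit order.  Weight matrices
are shifted by their joint minimum beforehand (modularity needs
non-negative weights; the shift preserves ordering and treats both
conditions identically).

The differential modularity of a treated network is
D = max(0, w_treated − E) with E the control edge weight rescaled by the
treated/control total-weight ratio of the edge's baseline community pair.
This expectation is exactly the control weight when treated equals control
(so self-comparison yields an identically zero matrix and no modules), and
is homogeneous of degree one under joint rescaling of both networks.

Because D is a floored difference of dense matrices, roughly half its
entries are small positive noise; entries at or below the 0.8 quantile of
the positive scores are discarded before aggregation.  Module aggregation
then warm-starts from the baseline partition and re-aggregates only nodes
with no remaining differential mass inside their baseline community.  This
anchoring is deliberate: re-optimizing communities freely on each drug's D
makes the module inventory incomparable across drugs (the cross-community
noise mass moves nodes arbitrarily per drug), which destroys the
cross-drug matching the OMU system depends on.  When no initial partition
is supplied (standalone use), the search is unconstrained.  Communities
with fewer than 2 surviving edges are dropped as singleton artifacts.

## OMU system

Cross-drug module pairs are visited in descending Jaccard similarity of
their edge sets (ties broken by lexicographic pair id).  A qualifying pair
(J ≥ 0.25) contributes its shared edge set: it either extends the first
existing OMU whose structure it overlaps (the structure narrowing to the
intersection, converging onto the edge core common to the member set) or
founds a new OMU.  Modules with no qualifying partner become singleton
OMUs.  An earlier variant additionally required the shared set to resemble
the narrowed structure (J ≥ 0.25 against the core); that guard made the
number of OMUs grow with the number of module pairs rather than the number
of recurring programs and was dropped.

Mean GRmax of an OMU is Σ_members GR_s·X_member / Σ_{distinct samples}
Y_total(s): each member contributes its sample's GRmax weighted by the
share of the sample's differential mass it carries.  The denominator counts
each member sample once, which keeps the quantity in [−1, 1] and makes it
invariant to zero-weight duplicate members.

## Balance selection and regression

OMUs are clustered by average linkage on |Δ mean GRmax| (input order is
canonicalized first, so the tree is permutation-invariant; at every node
the left subtree is the lower-centroid side).  The ILR balance at a node is
computed on the vector's proportions.  Two zero-handling modes exist:

* positive-part (the operation's default): geometric means over the
  positive components only, with the √(n_L·n_R/(n_L+n_R)) coefficient
  counting those components; undefined (an explicit sentinel, never a
  silent NaN) when a side has none;
* pseudocount (the fitted pipeline's default, ε = 0.05 on the proportion
  scale): every component participates.  Sparse OMU vectors make
  positive-part balances frequently undefined and give every sample its
  own coefficient, which adds variance unrelated to phenotype; the
  pseudocount mode keeps the coefficient constant and every sample
  scorable, at the cost of an imputation scale.  ε = 0.05 is of the order
  of a typical non-zero proportion in a system of a few dozen OMUs.

Candidate balance points are internal nodes with centroid mean GRmax in
[−0.5, 0.5], at least 2 OMUs per side (a one-OMU side cannot express a
combination push and makes DGIS degenerate; the floor is waived when no
node satisfies it), and defined balances for ≥ 90% of samples.  The
candidate maximizing |Pearson r| against GRmax wins (ties: deeper node,
then smaller id); a `use_root` mode skips the search and uses the root,
the reading under which every OMU participates.  GRmax is regressed on the
balance by ordinary least squares.

## Combination scoring

Combined vectors take the component-wise maximum (each drug acts on an OMU
independently; the larger effect dominates) and are renormalized; a `sum`
rule is available for sensitivity analysis.  GIS = intercept + slope·b at
the fitted node; being an extrapolation it is not confined to [−1, 1].
DGIS applies the three-case rule with inclusive boundaries, which makes
self-pairs exactly zero through the identity chain idempotent-combine →
equal GIS → middle case.  Ranking is ascending DGIS with (GIS, pair)
tie-breaks.

## ZIP scoring

A combination matrix must carry zero-concentration margins.  The delta per
interior cell is observed inhibition minus the independence expectation
y₁ + y₂ − y₁y₂ of the monotherapy effects; the summary is the mean interior
delta × 100 (percentage points), with > 5 called synergistic.  By default
y₁, y₂ are the observed margins, so a matrix equal to its own independence
expectation scores exactly zero; `smooth_margins=True` substitutes bounded
four-parameter-logistic fits (lo, hi ∈ [0, 1], EC50 within the dose range
×[0.01, 100], slope ∈ (0, 10], least squares with tight tolerances,
monotone-interpolation fallback on non-convergence), which is preferable on
noisy margins.  GR values use GR = 2^(k_c/k_0) − 1 with growth rates
k = ln(x_t/x_0)/t (t in hours, 72 h assay default); GRmax is the minimum
over tested concentrations.

## Enrichment

The top-k screen outcome (k₁ hits in s₁ pairs) and the random-sample
outcome (k₂ in s₂) are modelled as two draws from one unknown synergy
proportion M.  The binomial MLE is located numerically on (0, 1) and
coincides with the pooled proportion (k₁+k₂)/(s₁+s₂); the likelihood value
at the maximum is reported.  A finite-population variant maximizes the
product of two hypergeometric pmfs over the integer number of synergistic
pairs in a population of N; both variants are reported because the
sampling-without-replacement reading is equally natural for a fixed pair
pool.

## Synthetic studies

The generator plants a block-structured ground truth: `n_planted_modules`
TF/gene blocks wired densely in the prior (within-block edge probability
0.85 vs 0.04 across) and in the PPI (0.6 vs 0.05).  Blocks 0 and 1 are
death-associated.  Each drug up-regulates both death blocks with total
magnitude 2.5·e_d (e_d ~ U(0.15, 1), split between the two blocks) and
each neutral block independently with probability 0.75 and amplitude
U(0.4, 1.2); only a random 70% of a block's genes respond, with gene
loadings U(0.5, 1.5), so perturbations are heterogeneous within a block
the way real regulons are.  GRmax is a decreasing linear map of e_d over
`grmax_range` plus N(0, noise_sd), clipped to [−1, 1].  Planted synergy
pairs receive complementary death programs — the split shifts to
0.5 ± min(0.5, 2·strength) in opposite directions — and a death-activity
floor e_d ≥ 0.6, encoding the idea that a synergistic pair consists of two
active drugs hitting complementary death programs; their dose–response
matrices additionally receive the interaction strength on top of the
independence expectation.  Dose–response matrices are built from 4PL
monotherapy curves whose plateau is (1 − GRmax)/2, EC50 log-normal, slope
U(0.8, 2), five log-spaced doses around the EC50 plus the zero margin.
All randomness descends from one integer seed through fixed per-component
substreams, so studies are bit-reproducible and any component can be
regenerated independently.

**What passing tests show — and don't.**  The synthetic data reproduce the
statistical *structure* the method assumes (drugs perturb recurring
modules; death-module activity tracks GRmax; combinations act
independently unless an interaction is planted).  They do not emulate
L1000 landmark-gene inference, plate effects, dose-dependent
transcriptional responses, or regulatory rewiring that changes edge signs
rather than module activity.  Recovery results on these studies therefore
validate the pipeline's internal consistency and sensitivity, not its
performance on any real screen.

## Problem sizes and defaults

Default studies use 20–30 drugs, 30 TFs, 200 genes and 6 blocks — large
enough for non-trivial community structure and sparse vectors, small
enough that a full study fits in about a second of compute.  The
stochastic recovery checks run 10 seeded 30-drug studies (|r| ≥ 0.6
criterion) and 50 seeded 20-drug replicates for the ranking properties.
Key defaults: gate blend 0.8, gate power 2, denoise quantile 0.8, module
min_edges 2, OMU min_similarity 0.25, balance pseudocount 0.05, candidate
centroid bounds ±0.5, ZIP threshold 5, top-k 30.

## Known limitations

* The per-condition co-expression gate is a modelling device for the
  single-profile setting, not an estimator of condition-specific
  correlation; with replicate expression columns a true per-condition
  correlation would be preferable.
* The anchored module aggregation trades some per-drug adaptivity for
  cross-drug comparability; drugs that genuinely reorganize communities
  (rather than re-weighting them) will be under-segmented.
* Mean-GRmax ordering of OMUs is noisy when module weights are nearly
  proportional across samples; the balance-point search can then prefer
  idiosyncratic contrasts, which is why candidate nodes are required to
  have at least two OMUs per side.
* ZIP scoring here is the documented independence-delta summary, not a
  reimplementation of any particular package's potency-shift fitting;
  scores on noisy matrices will differ in detail from such tools.
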