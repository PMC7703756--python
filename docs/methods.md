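# Methods

## Problem setting and model

Given a genes × samples expression matrix and per-term binary gene
annotations, the package learns a term-specific diagonal metric for
co-expression. Each gene's expression vector is centered to mean zero
and scaled to unit L2 norm; on such vectors the plain inner product
equals the Pearson correlation, and the learned similarity generalizes
it to a weighted inner product S_w(xᵢ,xⱼ) = Σₘ wₘ x̃ᵢₘ x̃ⱼₘ with one
non-negative weight per sample. The weights are chosen to maximize
Welch's two-sample t-statistic between the similarity distributions of
co-annotated (p–p) and mixed (p–n) gene pairs, minus an L1 penalty:

    min_w  −α t(w) + (1−α) Σₘ wₘ,   wₘ ≥ 0,  α ∈ (0,1).

Pairs in which neither gene carries the term (n–n) are excluded from
the objective: such genes may be strongly co-expressed for a different
process, so their similarity carries no information about the term
under study. The t-statistic is used purely as a separability score;
no distributional assumptions are made and no p-values are derived
from it (pair similarities are neither independent nor Gaussian).

Key property: t(w) is invariant to positive rescaling of w (both the
mean difference and the pooled standard deviation are 1-homogeneous).
The L1 term is therefore the only force fixing the scale of w, and it
is what drives the weights of uninformative samples to exactly zero.
"Selected" samples are those with wₘ > 1e-8 × max(w); numerical
optimizers rarely return exact zeros, and a relative threshold keeps
the accounting invariant to the arbitrary overall scale.

## Sufficient statistics

Because S_w is linear in w, the per-group pair mean is linear and the
pair second moment is a quadratic form in w. With P/Q the positive and
negative index sets, p = Σ_{i∈P} x̃ᵢ, q = Σ_{i∈Q} x̃ᵢ, Gᴾ = XᴾᵀXᴾ,
Gꟴ = XꟴᵀXꟴ and H = (Xᴾ²)ᵀ(Xᴾ²) (elementwise square):

    Σ_pp S_w      = wᵀU,        U    = (p² − diag Gᴾ)/2
    Σ_pn S_w      = wᵀV,        V    = p ∘ q
    Σ_pp S_w²     = wᵀM_pp w,   M_pp = ((Gᴾ)² − H)/2
    Σ_pn S_w²     = wᵀM_pn w,   M_pn = Gᴾ ∘ Gꟴ

so each objective/gradient evaluation costs O(f²) in the number of
samples f, independent of the number of gene pairs (which grows
quadratically in genes). Variances use the unbiased N−1 denominator,
matching the standard Welch statistic; the brute-force oracle used in
the tests applies the same convention. When the four f×f matrices
would exceed a configurable memory cap (default 2 GB), the statistics
are instead estimated from a seeded uniform subsample of explicit
pairs (default cap 100 000 per group); the exact moments are the
default and the tested path.

## Optimization

Non-negativity is enforced with box constraints (lower bound 0 per
coordinate) in L-BFGS-B; a quasi-Newton method with bounds is the
natural realization of "BFGS subject to wₘ ≥ 0" and avoids the extra
non-convexity a softplus/square reparameterization would introduce.
The start point is all-ones — exactly the unweighted inner product,
i.e. plain-PCC behavior — making the fit deterministic with no RNG.
The analytic gradient follows from the quadratic forms above and is
verified against central finite differences (relative error < 1e-5).

Degenerate denominators: since t is scale-invariant, the optimizer may
legitimately shrink ‖w‖ so that the raw variances fall below any fixed
absolute floor while t stays well-defined; an absolute degeneracy
cutoff would spuriously error mid-optimization. The implementation
therefore treats the statistic as degenerate (t = 0, zero gradient)
only when the denominator is (near-)zero *and* the group means agree
to 1e-12 — e.g. constant expression — and raises only for an exactly
zero denominator with unequal means.

## Global variant

The term-agnostic variant redefines p–p as "shares at least one
informative term" and p–n as "shares none", fitting a single weight
vector for all terms. Two conventions make this well-posed: (1) terms
annotated to every gene (the ontology root after true-path
propagation, when all genes are annotated) are ignored when deciding
sharing, otherwise every pair would trivially be p–p; (2) pairs in
which neither gene carries any informative annotation are excluded —
they are the n–n analogue, and excluding them makes the global
partition coincide with the term-specific one on a single-term corpus.
Because the global p–p set has no product structure, this variant uses
the explicit-pair (subsampling) statistics path.

## Preprocessing

The count pipeline mirrors a standard RNA-seq co-expression
preparation, in this order: drop samples with fewer than 10⁷ mapped
reads (column sums proxy for mapped reads unless metadata supplies
them; thresholds are strict-less-than removals); drop genes with
maximum expression < 100 or median < 1 over the *surviving* samples
(the order matters and is enforced); log₂(count + 0.125) — the log
base only rescales rows uniformly and cancels after centering/scaling,
so it is configurable but immaterial; drop single-sample studies so
per-batch variances are estimable. A lightweight per-batch gene-wise
mean/variance standardization is available as an optional batch
adjustment; an externally batch-corrected (e.g. empirical-Bayes)
matrix can be supplied instead, and full batch-correction modelling is
out of scope.

## Annotations and specificity

GAF 2.x parsing keeps the Biological Process aspect, drops
NOT-qualified rows and (by default) IEA evidence. Annotations are
propagated over is_a and part_of (standard GO practice). Resnik IC is
−ln of the relative annotation frequency after propagation (natural
log; the base uniformly rescales IC-weighted averages and changes no
ranking). Terms need a minimum number of positives in the training
genes to be fitted (default 5; the p–p variance alone requires ≥ 2 p–p
pairs, i.e. ≥ 3 positives when combined with CV splitting).

## Prediction and evaluation

k-NN guilt-by-association: the score of a test gene for a term is the
fraction of its k nearest training genes annotated with the term.
Neighbor order is by descending similarity (or ascending Mutual Rank),
with ties broken by ascending training-gene index after a stable sort,
so scores depend only on the similarity ranking. Mutual Rank uses the
geometric mean of the two reciprocal neighbor ranks (ATTED-II
convention; arithmetic mean available), average ranks for ties, and
the diagonal excluded. ROC AUC is the rank-based (Mann–Whitney)
version with average ranks for tied scores. A fold's average includes
a term only when both classes occur among its test genes; skipped
terms are reported so that averages are comparable across methods
within a fold.

Nested CV: outer folds (default 3) estimate generalization on unseen
genes; inner folds (default 3) on the training genes select k (grid
{1, 3, 5, 11, 21, 51}, capped at the training size) and, for the
learned metric, α (grid {0.5, 0.9, 0.99, 0.999}). The pair-moment
matrices are built once per (term, fold) and shared across the α grid.
The hybrid classifier uses Mutual Rank's predictions for a term when
MR's *training* ROC AUC is strictly above 0.8 (configurable) and the
learned metric's otherwise; MR can also be applied on top of the
learned similarity matrix.

## Simulator

Each simulated term gets a disjoint, contiguous block of samples.
Positive genes follow a one-factor model inside their block,
x = √ρ·s + √(1−ρ)·ε with a shared per-sample factor s and independent
standard Gaussian noise, giving expected within-block correlation ρ
between positive genes; all other entries are N(0,1) noise. This is
the minimal generative law realizing a target within-block
correlation. Defaults are desk-scale — 1000 genes × 600 samples, 3
terms, 50 positives per term, 100-sample blocks, ρ = 0.7 — with a
7000 × 3000 preset (`full_scale_spec`) for full-scale replication.
Data are emitted directly in continuous log-space form; count-level
realism (negative-binomial sampling, zero inflation, batch structure)
is deliberately not modelled, so passing tests demonstrate recovery of
block-structured correlation signal, not robustness to count noise or
batch confounding in real compendia.

A note on regimes: what makes the all-sample PCC fail is *dilution* —
under the one-factor design the expected all-sample correlation of a
positive pair is ρ·b/f (block size b, f samples) against a null PCC
spread of ~1/√f. At 100 informative of 600 samples that signal
(≈ 0.117) stands ~3 null SDs out, so the plain PCC classifier already
saturates and sample weighting cannot add headroom; the regime where
few samples drive co-expression corresponds at desk scale to b ≈ 20 of
600 (≈ 1.4 SDs), where the learned metric clearly outperforms the
all-sample PCC and approaches the informative-block ("ground truth")
PCC. Both regimes are exercised in the tests.

## Experiments bundled with the package

* Label-permutation null: permuting the gene-to-term assignment and
  re-running the nested-CV pipeline yields mean held-out AUC at the
  0.5 chance level for both PCC and the learned metric — the method
  does not manufacture signal. Run at 1000 genes × 600 samples, 3
  terms, 20 permutations, with reduced grids (k ∈ {1, 5, 21, 51},
  α ∈ {0.5, 0.99}, 3 outer / 3 inner folds) to keep a single-CPU run
  in the minutes range; `scripts/acceptance.py` recomputes it from
  scratch.
* Block-recovery benchmark: train/validation/test gene split, per-term
  selection of (α, k) on validation genes, comparing PCC, the learned
  metric, and the PCC restricted to the true informative block.

## Known limitations

* Negative co-expression is penalized, not exploited: genes with
  opposite expression patterns in the same process lower t(w).
* Term-specific fitting ignores correlations between terms imposed by
  the ontology; the global variant trades specificity for a shared
  metric.
* The learned similarity is not bounded to [−1, 1] and is not
  comparable across terms; only within-term rankings are meaningful
  (sufficient for k-NN).
* Very frequent terms give the fit little to separate (most pairs are
  p–p) and the learned metric tends toward the unweighted baseline.
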