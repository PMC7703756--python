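# mlc — Metric Learning for Co-expression

Predicting which genes participate in a biological process (a Gene
Ontology BPO term) from bulk RNA-seq compendia usually relies on
guilt-by-association: a gene inherits the annotations of its most
strongly co-expressed neighbors, with the Pearson correlation (PCC)
over *all* samples as the similarity. But in a heterogeneous compendium
only a subset of samples is informative for any given process, and the
remaining samples dilute the correlation signal. `mlc` learns, for each
GO term, a non-negative weight per expression *sample* so that the
weighted co-expression of genes sharing the term is maximally separated
from that of mixed pairs — simultaneously selecting the informative
samples and improving k-NN function prediction.

The package is aimed at computational biologists working on automatic
function prediction or condition-specific co-expression analysis, and
includes the full evaluation pipeline (nested cross-validation,
term-centric ROC AUC, Mutual Rank and per-term-k PCC baselines, hybrid
classifiers) plus a simulator with known informative-sample blocks.

## Model

Expression vectors are centered and scaled per gene,
x̃ᵢ = (xᵢ − x̄ᵢ)/‖xᵢ − x̄ᵢ‖, so that the plain inner product of two genes
equals their PCC. The learned similarity is the weighted inner product

    S_w(xᵢ, xⱼ) = Σₘ wₘ x̃ᵢₘ x̃ⱼₘ ,   wₘ ≥ 0,

with one weight per sample. For a term *l*, gene pairs are grouped into
p–p (both annotated with *l*), p–n (exactly one), and n–n (neither;
ignored — such genes may be co-expressed for *other* processes). The
weights maximize the Welch two-sample t-statistic between the p–p and
p–n similarity distributions,

    t(w) = (μ_pp − μ_pn) / sqrt(σ²_pp/N_pp + σ²_pn/N_pn),

subject to an L1 penalty that drives uninformative samples to exactly
zero:

    min_w  −α·t(w) + (1−α)·Σₘ wₘ ,   wₘ ≥ 0.

t(w) is invariant to rescaling of w, so the L1 term alone fixes the
scale; α ∈ (0,1) trades separability against sparsity and is tuned in
the inner CV loop. Because S_w is linear in w, all pair means and
variances are quadratic forms in w; they are accumulated once into
sample×sample moment matrices, making each objective/gradient
evaluation O(f²) independent of the number of gene pairs, and the
bound-constrained problem is solved with L-BFGS-B from an all-ones
start (= unweighted PCC behavior). A term-agnostic "global" variant
defines p–p as sharing at least one informative term.

Prediction: a test gene's score for a term is the fraction of its k
nearest training genes (under S_w, PCC, or Mutual Rank) annotated with
the term; performance is the per-term ROC AUC over held-out genes,
averaged plain or weighted by Resnik information content.

## Worked example

```python
from mlc import SimulationSpec, simulation_benchmark, weight_recovery_report

# 1000 genes x 600 samples, 3 terms; only 20 samples per term carry signal
spec = SimulationSpec(informative_block_size=20, seed=0)
res = simulation_benchmark(spec, seed=0)
print(res["mean_auc"])

ds, model = res["dataset"], res["models"]["T0"]
rep = weight_recovery_report(model, ds, "T0")
print(model.n_selected, rep.mean_w_in, rep.mean_w_out, rep.fisher_p)
```

Output:

```
{'pcc': 0.869, 'mlc': 0.999, 'gt': 0.999}
284 0.0151 0.0013 2.56e-03
```

With only 20 of 600 samples informative, the all-sample PCC classifier
reaches a mean held-out AUC of 0.87 while the learned metric reaches
0.999 — matching the "ground truth" classifier that is told which
samples are informative. The fitted weights concentrate on the true
block: the mean weight inside it (0.0151) is ~12× the outside mean
(0.0013), and the selected samples are significantly enriched for the
block (Fisher exact p ≈ 2.6×10⁻³).

A CLI covers the same pipeline from the shell:

```bash
mlc simulate --n-genes 1000 --n-samples 600 --block-size 20 --out-dir sim/
mlc fit --expression sim/expression.tsv --labels sim/labels.tsv --term T0 --out weights.tsv
mlc run --config config.yaml          # nested-CV evaluation, hashed manifest
```

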