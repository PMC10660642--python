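# grnrewire

Quantifying cell-type-specific, condition-dependent gene regulation from
single-cell expression data and prior knowledge.

When a perturbation — a disease variant, a knockout, a treatment — hits a
transcription factor (TF), the measurable consequences are rarely confined
to the TF's own expression. They show up as shifts in target-gene
expression, in the TF's inferred regulatory *activity*, in how strongly
each gene is *targeted* by the regulatory network of each cell type, in
the *community structure* of those networks, and in the *rewiring* of
specific TF–target–cofactor relationships. `grnrewire` implements that
entire analysis chain as a tested, reusable library for people studying
cell-type-specific regulation (e.g. a mutant vs. wild-type mouse tissue
profiled by snRNA-seq), together with a synthetic-data generator that
plants each kind of effect with full ground truth, so every stage can be
validated end to end without any external download.

## The models

**Differential expression.** Per cell type, case vs. control cells are
compared gene-by-gene with a two-sided Wilcoxon rank-sum test on
log-normalized values (exact enumeration when both groups have ≤ 8
observations, tie-corrected normal approximation otherwise). Genes must
pass an average |log₂FC| ≥ 0.1 gate to be tested; Bonferroni-adjusted
p < 0.05 defines significance.

**TF activity.** Given a signed regulon prior (TF → target, mode ±1), each
expression profile *y* is regressed on the gene × TF design matrix *X*:

&nbsp;&nbsp;&nbsp;&nbsp;*y* = β₀ + Σₜ βₜ Xₜ + ε,

and a TF's activity is the t-statistic of its coefficient. TFs with fewer
than 5 targets present in the matrix are dropped. Activities are averaged
per (TF, cell type, condition), z-scaled across TFs, and TFs are
prioritized by the percent change between conditions (above Q3: stronger
in the case; below Q1: stronger in the control).

**Network inference.** A TF × gene regulatory network per (cell type,
condition) is inferred by message passing that reconciles three evidence
layers — TF–gene motif prior, TF–TF protein interactions, gene–gene
coexpression — through a continuous Tanimoto similarity
T(x, y) = ⟨x, y⟩ / √(‖x‖² + ‖y‖² − |⟨x, y⟩|). Each iteration forms the
responsibility R = T(P, Wᵀ) and availability A = T(W, C) and damps

&nbsp;&nbsp;&nbsp;&nbsp;W ← (1 − α) W + α (R + A)/2,

with the P (protein) and C (coexpression) layers damped the same way
toward their W-implied similarities. Edge weights are z-score-like:
positive supports an interaction.

**Differential targeting.** A gene's targeting score is the sum of its
in-degree edge weights; the condition difference is z-scored within cell
type and genes strictly above Q3 are selected, with hypergeometric
enrichment against a focal gene set.

**Communities.** Single-network communities maximize Barber bipartite
modularity Q = (1/m) Σᵢⱼ [Aᵢⱼ − kᵢdⱼ/m] δ(cᵢ, cⱼ); differential
communities maximize the within-community sum of
Dᵢⱼ = w⁽ᶜᵃˢᵉ⁾ᵢⱼ/m₍case₎ − k⁽ᶜᵗʳˡ⁾ᵢ d⁽ᶜᵗʳˡ⁾ⱼ/m₍ctrl₎², scoring case edges
against a control-derived null. Focal-TF communities are compared across
cell types with the Jaccard index.

**Rewiring.** For each (focal-TF target that is also a protein of the
cooperativity layer, mechanism protein) pair, the presence (> 0) of the
regulatory edge and of the cooperativity edge is compared between
conditions and classified into four categories combining regulation
change with cooperation gained/lost.

## Worked example

```python
from grnrewire import synth
from grnrewire.preprocess import log_normalize, wilcoxon_de

truth = synth.plant_perturbation(synth.default_truth(seed=2), components={"de"})
adata = synth.simulate_counts(truth, 150, seed=2)
log_normalize(adata)
table = wilcoxon_de(adata, "excitatory", "mutant", "wt", lfc_min=0.1, alpha=0.05)
print(table[table.significant].sort_values("p_adj").head(3))
```

prints

```
 gene    log2fc        p_adj  pct_case  pct_ctrl
G0009 -1.214428 5.747598e-16  0.980000  1.000000
G0057  1.062116 2.047923e-14  1.000000  1.000000
G0062 -1.131253 5.869797e-13  0.973333  0.986667
```

— three of the genes planted at |log₂FC| = 1 in excitatory-like cells,
recovered with the correct sign (G0009 and G0062 down, G0057 up) and
Bonferroni-significant p-values; `pct_case`/`pct_ctrl` are the detection
fractions per condition. In this run 10/10 planted genes were recovered
with 2 extra calls.

The `examples/` directory has one short script per capability
(simulation, DE, TF activity, network inference, differential targeting,
communities + rewiring, full pipeline). The full pipeline is also a CLI:

```bash
grnrewire run-all --outdir out --seed 1
```

which writes DE tables, activity tables, six networks, targeting tables,
(differential) community partitions, the focal-community Jaccard matrix,
rewiring classifications, and a manifest with sha256 checksums — rerunning
with the same seed reproduces every file bit-exactly.

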