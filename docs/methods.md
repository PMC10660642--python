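# Methods

This note documents the models implemented in `grnrewire`, the parameter
choices that matter, the design decisions taken where the design was
genuinely open, and what the synthetic data does and does not show.

## Expression container and normalization

Expression travels as an `anndata.AnnData`: raw nonnegative integer counts
in `.X`, per-cell `cell_type`, `condition`, `sample_id` in `.obs`, and a
`lognorm` layer added by `log_normalize` as ln(1 + s·c/total) with
s = 10⁴ counts per cell (the standard single-cell convention). Cells with
zero total counts are rejected by name rather than silently dropped.

## Differential expression

Per cell type, all case cells are pooled against all control cells (the
marker-test convention; a `mode="pseudobulk"` switch averages per
`sample_id` first). The statistic is the two-sided Wilcoxon rank-sum test
on lognorm values:

- both groups ≤ 8: exact enumeration over all C(n+m, n) assignments of
  the midranks. Midranks make the enumeration valid under ties, which are
  ubiquitous in count data; this is why the exact path is written here
  rather than delegated to a generic implementation.
- otherwise: the tie-corrected normal approximation (scipy's
  `mannwhitneyu`).

log₂FC is the difference of log₂(mean(expm1(lognorm)) + 1) between groups
— the convention of the tool this stage mirrors, stated explicitly so the
|log₂FC| ≥ 0.1 gate is reproducible. Genes failing the gate are not
tested (p = NaN, `tested` False) and do not enter the multiplicity
correction, which is Bonferroni over tested genes by default
(Benjamini–Hochberg behind `correction="bh"`). Significance is
p_adj < 0.05. Defaults 0.1 / 0.05 / Bonferroni are fixed by the study
design this package operationalizes.

Pooling cells across replicates makes the test anti-conservative when
between-replicate mean variation exists (pseudoreplication): with the
generator's replicate jitter on, the global-null fraction of raw p < 0.05
is ~0.15 rather than 0.05. This is a property of the pooled design, not a
bug; the calibration and recovery studies in the test suite therefore run
the generator with `replicate_sigma=0` and only the DE component planted,
which is the faithful realization of "no effects but the planted ones".
The default pipeline keeps jitter on, as real data would.

## Gene-set scores

`module_score` is the binned-control score: genes are placed into 24
equal-frequency bins of mean lognorm expression; for each set member, up
to 100 control genes are sampled (seeded, without replacement) from the
member's bin; the score is mean(set) − mean(controls) per cell. It is
invariant to adding a constant to all values. `signature_score` is the
per-cell mean of sign × per-gene-centered lognorm expression over a
signed gene set — a deliberately simple signed-signature statistic (no
autocorrelation machinery).

## TF activity

The multivariate linear model regresses each profile on
[intercept | signed regulon matrix] by OLS; the activity is the
coefficient t-statistic (coefficient / standard error), which makes
activities invariant to rescaling the profile. Profiles are single cells
on lognorm values, averaged afterwards per (TF, cell type, condition).
TFs with fewer than five matched targets are dropped before fitting (and
reported). Rank-deficient designs are rejected with the collinear columns
named; zero-residual (perfect-fit) profiles yield NaN activities instead
of infinities.

Summaries: group means are z-scaled across TFs within each
(cell type, condition) — the scaling axis is an interpretation, chosen so
that a TF's activity is always read relative to its peers in the same
population. Percent change is 100·(case − control)/max(|control|, ε) with
ε = 10⁻⁸; degenerate control magnitudes produce a signed-infinite
sentinel excluded from the quartile ranking. Q1/Q3 flags are computed
over all finite (TF, cell type) changes in the run.

## Network inference

Priors: the motif (TF × gene) and PPI (TF × TF) matrices and the
coexpression matrix (Pearson, unit diagonal, zero-variance genes zeroed)
are normalized as the average of row-wise and column-wise z-scores
(zero-variance slices fall back to the overall z-score; a constant
matrix maps to zeros). Genes in expression but absent from the motif
prior keep all-zero prior columns.

Update loop (α = 0.1, tol = 10⁻⁵ on the mean absolute change of W,
max 200 iterations; all deterministic):

    R = T(P, Wᵀ);  A = T(W, C);  W ← (1−α)W + α(R+A)/2
    P ← (1−α)P + α·stab(T(W, W));  C ← (1−α)C + α·stab(T(Wᵀ, Wᵀ))

where T is the continuous Tanimoto similarity. Two numerical points about
`stab(·)`, the stabilization of the square co-updates:

1. **Self-similarity diagonal.** T grows with vector norm (T(x, x) = ‖x‖),
   so the bare damped loop diverges geometrically. Following the cited
   algorithm's convention, the diagonal of each square similarity update
   is replaced by the off-diagonal row std × (inner dimension) ×
   exp(2αt). The growing self-message freezes the loop and makes the
   change statistic fall below tol (typically ~50 iterations at the
   default sizes).
2. **Off-diagonal z-scoring.** The raw similarity of sparse nonnegative
   rows is positively offset; z-scoring the off-diagonal of each update
   keeps the co-evolved P and C layers zero-centered, so "positive weight
   = supported interaction" holds for the TF–TF cooperativity layer the
   rewiring stage consumes, not just for W.

α = 0 is accepted as a degenerate testing value (W is returned as the
normalized motif prior, exactly). The averaged (R + A)/2 term *is* the
responsibility/availability consensus; no separate post-hoc averaging is
performed, because that is the computation the damped update carries out
at every step.

## Differential targeting

targeting(g) = Σₜ W[t, g] including negative weights (a positive-only
flag exists for sensitivity analysis). diff = case − control;
normalization is the within-cell-type z-score; selection is strictly
above the linear-interpolation Q3 (ties at Q3 excluded — a deterministic
rule for a boundary the method leaves open). Identities maintained and
tested: Σ_g diff(g) equals the total edge-weight difference;
condition swap negates diff elementwise. Enrichment of the selected set
against a focal gene set is the upper-tail hypergeometric p.

## Communities

Single-network communities maximize Barber bipartite modularity on the
strictly positive edges (isolated nodes dropped with a report). The
optimizer is shared between the single-network and differential
objectives, both of the form max Σᵢⱼ Bᵢⱼ δ(cᵢ, cⱼ):

- seeded multi-restart (singleton-TF, all-singleton, and random
  initializations);
- alternating TF/gene label sweeps moving a node only on strict gain
  (ties resolve to the lowest community id; all-negative attachment
  isolates the node);
- greedy community merges while the merge gain is positive;
- a final refinement splitting each community into connected components
  of its nonnegative-contribution edge subgraph. The differential
  objective is degenerate — nodes absent from the control network attach
  to any community at exactly zero cost — and this pass canonically
  returns the finest among score-tied optima; it can never lower the
  score.

On all graphs with ≤ 6 nodes the optimizer attains the exhaustive-
enumeration optimum (tested); on 4-block bipartite SBMs (20 TFs ×
40 genes, p_in = 0.9, p_out = 0.05) it recovers the planted blocks with
ARI ≥ 0.9 in 100/100 seeds.

The differential objective uses control strengths for the null term, with
zero null contribution for nodes absent from the control; it is invariant
to uniformly rescaling either network. The focal community is the
community containing the focal TF; both TF and gene nodes enter the
cross-cell-type Jaccard comparison by default (`genes_only` restricts to
genes).

## Rewiring classification

"Presence" of an edge is weight strictly greater than 0 — the natural
null of z-score-like networks (threshold configurable). Each axis changes
between control and case as gained/lost/stable. The committed 16-row
truth table labels pairs by the cooperation axis: `cooperation_gained` /
`cooperation_lost`, each with a `regulation_change_` prefix when the
regulation axis also moved; cooperation-stable pairs get
`regulation_change_only` or `unchanged` and are excluded from the
four-category report. Swapping case and control maps gained ↔ lost on
both axes. The cooperativity input defaults to the inferred model's
per-condition TF–TF layer; a user-supplied per-condition protein network
is accepted instead.

## Synthetic data

The generator emulates the statistical shape of a two-condition,
multi-cell-type single-nucleus study. Defaults (chosen once as a
realistic desk-scale study): 12 TFs, 80 genes (the first 12 gene slots
are the TF genes themselves, so rewiring targets exist as both genes and
proteins), 3 cell types, 150 cells per cell type per condition, expected
depth 2000 counts/cell, NB dispersion 2, lognormal(σ=0.3) library sizes,
3 pseudo-replicates per condition via lognormal(σ=0.1) per-gene mean
jitter, 5% marker genes per cell type at 5× baseline. Motif density 0.2,
PPI density 0.3, regulon modes +1 with probability 0.7.

Planted effects and how they are realized:

- **DE**: chosen non-marker genes get a 2^±lfc case multiplier.
- **Active TF**: the regulon's best-covered non-focal TF; its targets are
  shifted by 0.5·mode log₂-units in case cells of the affected cell
  types.
- **Network module**: 3 TFs × 8 genes whose case motif weights are
  boosted and whose genes share a case-only lognormal latent factor. A
  single-TF module would be unrecoverable by differential targeting *in
  principle*: column z-scoring of the prior cancels single-column sum
  changes, so the module spans several TFs, as a real differential
  community does.
- **Rewiring**: the regulation axis is the focal-TF motif edge per
  condition plus co/anti-expression of the target gene with the focal
  TF's expression program; the cooperation axis is the PPI prior edge
  plus condition-dependent sharing of a dedicated motif support block and
  co/anti-regulated expression programs between target and mechanism
  proteins. This realization matches what the converged model measures —
  cooperativity is regulatory-profile similarity — and yields 100%
  category recovery across seeds and cell types in the tests.

Not emulated: ambient RNA, doublets, batch effects, realistic gene names,
empty droplets, UMI saturation. Passing tests therefore demonstrate
method correctness and recoverability under the declared noise model, not
robustness to those artifacts.

## Problem sizes and determinism

Verification studies use desk-scale sizes chosen to make the statistical
properties measurable with comfortable margins: 500 genes × 200 cells per
group × 10 seeds for DE calibration/recovery, 50 simulations for activity
sign recovery, 100 SBM seeds and 50 + 20 planted/null differential-
community seeds, and the default study for end-to-end runs. Every source
of randomness is an explicit integer seed; the pipeline manifest records
config, seeds, and sha256 checksums of all outputs, and a rerun with the
same config reproduces every file bit-exactly.

## Known limitations

- The message-passing consensus is a fixed-point heuristic; convergence
  to tol is checked and flagged but not guaranteed for adversarial
  priors.
- The community optimizer is a local-search heuristic with restarts;
  optimality is only certified on small graphs (by enumeration) and
  planted benchmarks (by recovery).
- Pooled-cell DE inherits pseudoreplication anti-conservatism when
  replicate-level variation is present (see above); the pseudobulk switch
  trades power for calibration.
- Percent-change prioritization of TF activity is unstable when the
  control-side scaled activity is near zero; such TFs are reported with a
  sentinel and excluded from quartile ranking rather than silently
  ranked.
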