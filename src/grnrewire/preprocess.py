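"""Normalization, differential expression, and gene-set scoring.

Differential expression follows the marker-test convention of the standard
single-cell toolkits: per cell type, cells of the case condition are compared
against cells of the control condition with a two-sided Wilcoxon rank-sum
test on log-normalized values. Genes whose average log2 fold change fails the
gate are not tested at all; multiplicity correction (Bonferroni by default)
is applied over the genes actually tested. For small groups (both sides
<= 8 cells) the p-value is computed by exact enumeration over all group
assignments of the midranks, which stays valid under ties.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import anndata as ad
from scipy import stats

__all__ = [
    "log_normalize",
    "wilcoxon_de",
    "rank_sum_pvalue",
    "module_score",
    "signature_score",
    "detection_fraction",
]

EXACT_MAX_N = 8


def _require_lognorm(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("log-normalized layer missing; run log_normalize first")
    return np.asarray(adata.layers["lognorm"])


def log_normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Add a ``lognorm`` layer: ln(1 + scale * count / cell_total).

    Rejects cells with zero total counts by name."""
    X = np.asarray(adata.X, dtype=float)
    if np.any(X < 0) or not np.allclose(X, np.round(X)):
        raise ValueError("raw layer must contain nonnegative integer counts")
    totals = X.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        names = ", ".join(adata.obs_names[zero[:5]])
        raise ValueError(f"cells with zero total counts: {names}")
    adata.layers["lognorm"] = np.log1p(scale * X / totals[:, None])
    return adata


def rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration over all C(n+m, n) group assignments when both groups
    have <= 8 observations (midranks, so ties are handled exactly);
    otherwise the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    if n <= EXACT_MAX_N and m <= EXACT_MAX_N:
        ranks = stats.rankdata(np.concatenate([x, y]))
        obs = ranks[:n].sum()
        center = n * (n + m + 1) / 2.0
        dev = abs(obs - center)
        hits = total = 0
        for comb in itertools.combinations(range(n + m), n):
            s = ranks[list(comb)].sum()
            total += 1
            if abs(s - center) >= dev - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _seurat_log2fc(ln_case: np.ndarray, ln_ctrl: np.ndarray) -> float:
    # log2(mean(expm1(lognorm)) + 1) difference, the marker-test convention
    return float(
        np.log2(np.expm1(ln_case).mean() + 1.0) - np.log2(np.expm1(ln_ctrl).mean() + 1.0)
    )


def wilcoxon_de(
    adata: ad.AnnData,
    cell_type: str,
    case: str,
    control: str,
    lfc_min: float = 0.1,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-gene DE table for one cell type (case vs. control).

    Returns the full table of tested genes; ``significant`` marks rows with
    ``p_adj < alpha``. Genes with |log2fc| below ``lfc_min`` are excluded
    from testing (``tested`` False, p = NaN). ``mode='pseudobulk'`` averages
    lognorm values per sample_id before ranking."""
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    L = _require_lognorm(adata)
    ct_mask = (adata.obs["cell_type"] == cell_type).values
    case_mask = ct_mask & (adata.obs["condition"] == case).values
    ctrl_mask = ct_mask & (adata.obs["condition"] == control).values
    if case_mask.sum() < 3 or ctrl_mask.sum() < 3:
        raise ValueError(
            f"cell type {cell_type!r} needs >= 3 cells in both conditions "
            f"(found {case_mask.sum()} case, {ctrl_mask.sum()} control)"
        )
    Lc_full, Lk_full = L[case_mask], L[ctrl_mask]
    Lc, Lk = Lc_full, Lk_full
    Xc_raw = np.asarray(adata.X)[case_mask]
    Xk_raw = np.asarray(adata.X)[ctrl_mask]
    if mode == "pseudobulk":
        sc = adata.obs.loc[case_mask, "sample_id"].values
        sk = adata.obs.loc[ctrl_mask, "sample_id"].values
        Lc = np.vstack([Lc_full[sc == s].mean(axis=0) for s in pd.unique(sc)])
        Lk = np.vstack([Lk_full[sk == s].mean(axis=0) for s in pd.unique(sk)])
    elif mode != "pooled":
        raise ValueError("mode must be 'pooled' or 'pseudobulk'")

    genes = adata.var_names
    rows = []
    for j, g in enumerate(genes):
        lfc = _seurat_log2fc(Lc_full[:, j], Lk_full[:, j])
        tested = abs(lfc) >= lfc_min
        p = rank_sum_pvalue(Lc[:, j], Lk[:, j]) if tested else np.nan
        rows.append(
            {
                "gene": g,
                "cell_type": cell_type,
                "log2fc": lfc,
                "p": p,
                "tested": tested,
                "pct_case": float((Xc_raw[:, j] > 0).mean()),
                "pct_ctrl": float((Xk_raw[:, j] > 0).mean()),
                "direction": "up" if lfc > 0 else "down",
            }
        )
    table = pd.DataFrame(rows)
    n_tested = int(table["tested"].sum())
    p_adj = np.full(len(table), np.nan)
    if n_tested:
        tested_idx = table.index[table["tested"]]
        raw = table.loc[tested_idx, "p"].values
        if correction == "bonferroni":
            adj = np.minimum(raw * n_tested, 1.0)
        else:
            adj = _benjamini_hochberg(raw)
        p_adj[tested_idx] = adj
    table["p_adj"] = p_adj
    table["significant"] = table["tested"] & (table["p_adj"] < alpha)
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def module_score(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score per cell (AddModuleScore convention).

    Genes are placed in ``n_bins`` equal-frequency bins by their mean
    lognorm expression; for each set member, ``n_ctrl`` control genes are
    sampled (without replacement, capped at bin size) from the member's bin.
    Score = mean(set) - mean(controls) per cell."""
    L = _require_lognorm(adata)
    genes = list(adata.var_names)
    members = [g for g in gene_set if g in genes]
    if not members:
        raise ValueError("gene set has no overlap with the matrix genes")
    gene_pos = {g: j for j, g in enumerate(genes)}
    avg = L.mean(axis=0)
    n_bins_eff = min(n_bins, len(genes))
    # equal-frequency bins of the average expression (rank-based)
    bins = pd.qcut(pd.Series(avg).rank(method="first"), n_bins_eff, labels=False).values
    rng = np.random.default_rng(seed)
    ctrl_idx: set[int] = set()
    for g in members:
        b = bins[gene_pos[g]]
        pool = np.where(bins == b)[0]
        take = min(n_ctrl, len(pool))
        ctrl_idx.update(rng.choice(pool, size=take, replace=False).tolist())
    member_idx = [gene_pos[g] for g in members]
    ctrl = np.array(sorted(ctrl_idx))
    return L[:, member_idx].mean(axis=1) - L[:, ctrl].mean(axis=1)


def signature_score(
    adata: ad.AnnData, signed_set: list[tuple[str, int]]
) -> np.ndarray:
    """Signed signature score: per-cell mean of sign x (lognorm value centered
    per gene across cells) over the set members present in the matrix."""
    L = _require_lognorm(adata)
    gene_pos = {g: j for j, g in enumerate(adata.var_names)}
    idx, signs = [], []
    for g, s in signed_set:
        if g in gene_pos:
            if s not in (-1, 1):
                raise ValueError(f"sign for {g!r} must be -1 or +1")
            idx.append(gene_pos[g])
            signs.append(s)
    if not idx:
        raise ValueError("signed set has no overlap with the matrix genes")
    centered = L[:, idx] - L[:, idx].mean(axis=0, keepdims=True)
    return (centered * np.asarray(signs)[None, :]).mean(axis=1)


def detection_fraction(
    adata: ad.AnnData, cell_type: str, gene: str, case: str, control: str
) -> tuple[float, float]:
    """Fraction of cells with nonzero raw counts, per condition."""
    if gene not in adata.var_names:
        raise KeyError(f"unknown gene {gene!r}")
    j = list(adata.var_names).index(gene)
    X = np.asarray(adata.X)
    ct = (adata.obs["cell_type"] == cell_type).values
    out = []
    for cond in (case, control):
        mask = ct & (adata.obs["condition"] == cond).values
        if mask.sum() == 0:
            raise ValueError(f"no cells of type {cell_type!r} in condition {cond!r}")
        out.append(float((X[mask, j] > 0).mean()))
    return out[0], out[1]
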