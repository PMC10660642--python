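"""Gene targeting scores and differential targeting between conditions.

A gene's targeting score is the sum of all its in-degree edge weights in a
regulatory network (negative weights included — they count as evidence
against regulation and pull the total down). Differential targeting is the
per-gene difference case minus control; genes strictly above the third
quartile of the differential score within a cell type are selected, and
their overlap with a focal gene set is assessed by an upper-tail
hypergeometric test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .grn import Grn

__all__ = [
    "gene_targeting",
    "differential_targeting",
    "hypergeometric_enrichment",
    "targeting_summary",
]


def gene_targeting(grn: Grn, positive_only: bool = False) -> pd.Series:
    """Per-gene sum of in-degree edge weights (column sums of the TF x gene
    weight matrix). ``positive_only`` restricts the sum to positive edges
    (sensitivity analysis)."""
    W = grn.weights
    if positive_only:
        W = np.where(W > 0, W, 0.0)
    return pd.Series(W.sum(axis=0), index=grn.genes, name="targeting")


def differential_targeting(
    case: Grn,
    ctrl: Grn,
    focal_set: set[str] | None = None,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Differential targeting table for one cell type.

    diff = score_case - score_ctrl per gene; diff_normalized is the within-
    cell-type z-score of diff; ``selected`` flags genes with diff strictly
    above the third quartile (linear-interpolation quantile; ties at Q3 are
    excluded)."""
    if set(case.genes) != set(ctrl.genes):
        only_case = sorted(set(case.genes) - set(ctrl.genes))
        only_ctrl = sorted(set(ctrl.genes) - set(case.genes))
        raise ValueError(
            f"gene universes differ; only in case: {only_case[:5]}, "
            f"only in control: {only_ctrl[:5]}"
        )
    s_case = gene_targeting(case, positive_only)
    s_ctrl = gene_targeting(ctrl, positive_only).reindex(s_case.index)
    diff = s_case - s_ctrl
    sd = diff.values.std()
    z = (diff.values - diff.values.mean()) / sd if sd > 0 else np.zeros(len(diff))
    q3 = np.percentile(diff.values, 75)  # linear interpolation
    table = pd.DataFrame(
        {
            "gene": s_case.index,
            "cell_type": case.cell_type,
            "score_case": s_case.values,
            "score_ctrl": s_ctrl.values,
            "diff": diff.values,
            "diff_normalized": z,
            "selected": diff.values > q3,
        }
    )
    table["in_focal_set"] = (
        table["gene"].isin(focal_set) if focal_set is not None else False
    )
    return table


def hypergeometric_enrichment(
    selected: set[str], focal_set: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric p-value of the selected/focal overlap."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected <= universe or not focal_set <= universe:
        raise ValueError("selected and focal_set must be subsets of the universe")
    M, K, n = len(universe), len(focal_set), len(selected)
    k = len(selected & focal_set)
    # P(X >= k) for X ~ Hypergeom(M, K, n)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    return k, min(p, 1.0)


def targeting_summary(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Dot-plot-ready per-cell-type summary: total positive and negative
    differential-targeting mass, mean normalized score, and gene counts."""
    rows = []
    for t in tables:
        d = t["diff"].values
        rows.append(
            {
                "cell_type": t["cell_type"].iloc[0],
                "total_positive_diff": float(d[d > 0].sum()),
                "total_negative_diff": float(d[d < 0].sum()),
                "mean_normalized_diff": float(t["diff_normalized"].mean()),
                "n_genes_up": int((d > 0).sum()),
                "n_genes_down": int((d < 0).sum()),
                "n_selected": int(t["selected"].sum()),
            }
        )
    return pd.DataFrame(rows)
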