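"""TF activity from signed regulons via a multivariate linear model.

Each expression profile (a cell, or a pseudobulk sample) is regressed on the
signed TF-target design matrix: y ~ intercept + sum_t beta_t * mode_t. A
TF's activity in that profile is the t-statistic of its coefficient, so
activity is scale-free in the profile units and down-weights TFs whose
regulon fit is noisy. TFs with fewer than ``min_targets`` targets present in
the expression matrix are dropped before fitting.

Condition contrast: activities are averaged per (TF, cell type, condition),
z-scaled across TFs within each (cell type, condition), and TFs are
prioritized by the percent change of the scaled average activity between
conditions — above the third quartile (stronger in the case condition) or
below the first quartile (stronger in the control).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import anndata as ad

__all__ = [
    "build_design",
    "mlm_activity",
    "activity_per_cell",
    "summarize_activity",
]

PCT_EPS = 1e-8


def build_design(
    regulons: pd.DataFrame, genes: list[str], min_targets: int = 5
) -> tuple[pd.DataFrame, list[str]]:
    """Gene x TF signed design matrix from a (tf, target, mode) table.

    TFs with fewer than ``min_targets`` targets matched to ``genes`` are
    dropped and reported. Raises if nothing survives."""
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    required = {"tf", "target", "mode"}
    if not required <= set(regulons.columns):
        raise ValueError(f"regulon table needs columns {sorted(required)}")
    if regulons.duplicated(["tf", "target"]).any():
        dup = regulons[regulons.duplicated(["tf", "target"], keep=False)]
        raise ValueError(f"duplicate (tf, target) pairs: {dup[['tf', 'target']].values[:5].tolist()}")
    modes = regulons["mode"].astype(float)
    if not np.all(np.isfinite(modes)) or np.any(modes == 0):
        raise ValueError("regulon modes must be finite and nonzero")
    gene_pos = {g: j for j, g in enumerate(genes)}
    matched = regulons[regulons["target"].isin(gene_pos)]
    counts = matched.groupby("tf").size()
    keep = counts[counts >= min_targets].index.tolist()
    dropped = sorted(set(regulons["tf"]) - set(keep))
    if not keep:
        raise ValueError("no TF has enough matched targets; nothing to fit")
    keep = sorted(keep)
    tf_pos = {t: c for c, t in enumerate(keep)}
    mat = np.zeros((len(genes), len(keep)))
    sub = matched[matched["tf"].isin(tf_pos)]
    mat[
        [gene_pos[t] for t in sub["target"]],
        [tf_pos[t] for t in sub["tf"]],
    ] = sub["mode"].astype(float).values
    design = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=keep)
    return design, dropped


def mlm_activity(profiles: np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """OLS t-statistics of each TF coefficient, per profile.

    Parameters
    ----------
    profiles : (n_genes,) or (n_genes, n_profiles) expression values aligned
        with ``design`` rows.
    design : gene x TF signed matrix from :func:`build_design`.

    Returns a TF x profile DataFrame of t-values. Profiles with zero residual
    variance (perfect fit) yield NaN activities rather than infinities.
    """
    Y = np.asarray(profiles, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n_genes, n_prof = Y.shape
    if n_genes != design.shape[0]:
        raise ValueError("profile length does not match design rows")
    k = design.shape[1]
    if n_genes <= k + 1:
        raise ValueError("need more genes than TFs + intercept")
    X = np.column_stack([np.ones(n_genes), design.values])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = _collinear_columns(design)
        raise ValueError(f"design is rank deficient; collinear TF columns: {cols}")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ Y)  # (k+1, n_prof)
    resid = Y - X @ coef
    dof = n_genes - (k + 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    diag = np.diag(XtX_inv)[1:]  # skip intercept
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2[None, :] * diag[:, None])
        t = np.where(se > 0, coef[1:] / se, np.nan)
    return pd.DataFrame(t, index=design.columns, columns=range(n_prof))


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Name columns implicated in exact collinearity (duplicates first,
    falling back to the SVD null space)."""
    cols = design.columns
    vals = design.values
    dup_pairs = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            if np.array_equal(vals[:, a], vals[:, b]):
                dup_pairs.extend([cols[a], cols[b]])
    if dup_pairs:
        return sorted(set(dup_pairs))
    X = np.column_stack([np.ones(len(vals)), vals])
    _, s, vt = np.linalg.svd(X)
    null = vt[s.size - (s < s.max() * 1e-10).sum():] if (s < s.max() * 1e-10).any() else vt[-1:]
    involved = np.where(np.abs(null).max(axis=0)[1:] > 1e-8)[0]
    return sorted(cols[involved])


def activity_per_cell(
    adata: ad.AnnData, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell TF activity t-values from the lognorm layer (TF x cell)."""
    if "lognorm" not in adata.layers:
        raise ValueError("log-normalized layer missing; run log_normalize first")
    L = np.asarray(adata.layers["lognorm"])
    if list(adata.var_names) != list(design.index):
        design = design.reindex(adata.var_names).fillna(0.0)
    t = mlm_activity(L.T, design)
    t.columns = adata.obs_names
    return t


def summarize_activity(
    activities: pd.DataFrame,
    metadata: pd.DataFrame,
    case: str,
    control: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average, scale, and prioritize TF activities per cell type.

    Parameters
    ----------
    activities : TF x profile t-values (columns align with ``metadata`` rows).
    metadata : per-profile frame with ``cell_type`` and ``condition``.

    Returns
    -------
    profile_table : long frame (tf, cell_type, condition, activity,
        activity_scaled) — mean activity per group, then z-scored across TFs
        within each (cell_type, condition).
    change_table : (tf, cell_type, pct_change, priority) — percent change of
        the scaled average activity, case vs. control, with above_Q3 /
        below_Q1 flags computed over all finite (tf, cell_type) changes.
        Degenerate control magnitudes (< 1e-8) yield signed-infinite
        pct_change and are excluded from the quartile ranking.
    """
    if activities.shape[1] != len(metadata):
        raise ValueError("metadata rows must align with activity columns")
    md = metadata.reset_index(drop=True)
    rows = []
    for ct in pd.unique(md["cell_type"]):
        for cond in (case, control):
            mask = ((md["cell_type"] == ct) & (md["condition"] == cond)).values
            if mask.sum() == 0:
                continue
            mean_act = activities.iloc[:, mask.nonzero()[0]].mean(axis=1)
            for tf, a in mean_act.items():
                rows.append({"tf": tf, "cell_type": ct, "condition": cond, "activity": a})
    prof = pd.DataFrame(rows)
    skipped = []
    for ct in pd.unique(prof["cell_type"]):
        conds = set(prof.loc[prof["cell_type"] == ct, "condition"])
        if not {case, control} <= conds:
            skipped.append(ct)
    if skipped:
        import warnings

        warnings.warn(f"cell types missing a condition were skipped: {skipped}")
        prof = prof[~prof["cell_type"].isin(skipped)].reset_index(drop=True)
    if prof.empty:
        raise ValueError("no (cell_type, condition) group has profiles")

    def _zscale(v: pd.Series) -> pd.Series:
        a = v.values
        sd = a.std()  # population scale across TFs
        return pd.Series((a - a.mean()) / sd if sd > 0 else np.zeros_like(a), index=v.index)

    prof["activity_scaled"] = prof.groupby(["cell_type", "condition"])[
        "activity"
    ].transform(_zscale)

    piv = prof.pivot_table(
        index=["tf", "cell_type"], columns="condition", values="activity_scaled"
    ).reset_index()
    a_case, a_ctrl = piv[case].values, piv[control].values
    degenerate = np.abs(a_ctrl) < PCT_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (a_case - a_ctrl) / np.maximum(np.abs(a_ctrl), PCT_EPS)
    pct[degenerate] = np.sign(a_case[degenerate]) * np.inf
    change = pd.DataFrame(
        {"tf": piv["tf"], "cell_type": piv["cell_type"], "pct_change": pct}
    )
    finite = np.isfinite(pct)
    priority = np.array(["none"] * len(change), dtype=object)
    if finite.sum() >= 2:
        q1, q3 = np.percentile(pct[finite], [25, 75])
        priority[finite & (pct > q3)] = "above_Q3"
        priority[finite & (pct < q1)] = "below_Q1"
    change["priority"] = priority
    return prof, change
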