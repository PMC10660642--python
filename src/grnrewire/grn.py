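"""Message-passing gene regulatory network inference (PANDA-style).

Three layers of evidence — a TF x gene motif prior, a symmetric TF x TF
protein-interaction prior, and a gene x gene coexpression network — are
iteratively reconciled. Each iteration computes, via a continuous Tanimoto
similarity, the "responsibility" R (agreement between a TF's protein
neighborhood and the current regulatory network) and the "availability" A
(agreement between a gene's coexpression neighborhood and the network), and
damps the regulatory network toward their average:

    W <- (1 - alpha) * W + alpha * (R + A) / 2

The PPI and coexpression layers are damped the same way toward their
W-implied similarities, so all three layers co-evolve. Edge weights are
z-score-like interaction strengths: positive values support an interaction,
negative values count against it. The update is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PandaConfig",
    "Grn",
    "coexpression_network",
    "continuous_tanimoto",
    "normalize_prior",
    "panda_infer",
]


@dataclass
class PandaConfig:
    """Hyperparameters of the damped message-passing update.

    alpha: update rate in (0, 1]; alpha=0 is accepted as a degenerate
    fixed-point setting (the normalized motif prior is returned unchanged),
    useful for testing. tol: convergence threshold on the mean absolute
    change of W per iteration. max_iter: iteration cap."""

    alpha: float = 0.1
    tol: float = 1e-5
    max_iter: int = 200

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Grn:
    """Weighted TF x gene regulatory network for one (cell type, condition)."""

    tfs: list[str]
    genes: list[str]
    weights: np.ndarray
    cell_type: str = ""
    condition: str = ""
    iterations_run: int = 0
    converged: bool = False
    ppi_out: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.tfs), len(self.genes)):
            raise ValueError("weight matrix shape must be (n_tfs, n_genes)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("all edge weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (tf, gene, weight) edge table."""
        t, g = np.meshgrid(range(len(self.tfs)), range(len(self.genes)), indexing="ij")
        return pd.DataFrame(
            {
                "tf": np.asarray(self.tfs)[t.ravel()],
                "gene": np.asarray(self.genes)[g.ravel()],
                "weight": self.weights.ravel(),
            }
        )

    def as_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.tfs, columns=self.genes)


def coexpression_network(values: np.ndarray, genes: list[str]) -> pd.DataFrame:
    """Pearson correlation across cells (rows = cells, columns = genes).

    Zero-variance genes get zero off-diagonal entries and a unit diagonal
    instead of NaNs."""
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an (n_cells >= 3) x n_genes matrix")
    if X.shape[1] != len(genes):
        raise ValueError("gene names must align with matrix columns")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    bad = sd == 0
    C[bad, :] = 0.0
    C[:, bad] = 0.0
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=genes, columns=genes)


def continuous_tanimoto(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity between the rows of X and of Y.

    T(x, y) = <x, y> / sqrt(|x|^2 + |y|^2 - |<x, y>|); pairs where both
    vectors are zero map to 0. X is (n, k), Y is (m, k); returns (n, m)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"shared inner dimension required, got {X.shape} and {Y.shape}"
        )
    inner = X @ Y.T
    nx = (X**2).sum(axis=1)[:, None]
    ny = (Y**2).sum(axis=1)[None, :]
    denom_sq = nx + ny - np.abs(inner)
    out = np.zeros_like(inner)
    ok = denom_sq > 0
    out[ok] = inner[ok] / np.sqrt(denom_sq[ok])
    return out


def normalize_prior(W: np.ndarray) -> np.ndarray:
    """Average of row-wise and column-wise z-scores of each entry.

    Zero-variance rows/columns fall back to the overall z-score of the
    matrix (defined 0 for a constant matrix), so the output is always
    finite."""
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("prior entries must be finite")
    mu, sd = W.mean(), W.std()
    overall = (W - mu) / sd if sd > 0 else np.zeros_like(W)
    rsd = W.std(axis=1, keepdims=True)
    rmu = W.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rowz = np.where(rsd > 0, (W - rmu) / rsd, overall)
    csd = W.std(axis=0, keepdims=True)
    cmu = W.mean(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        colz = np.where(csd > 0, (W - cmu) / csd, overall)
    return 0.5 * (rowz + colz)


def _stabilize_diagonal(sim: np.ndarray, inner_dim: int, alpha: float, step: int) -> None:
    """Self-similarity damping of a co-evolving square similarity update.

    The diagonal is replaced by the off-diagonal row std scaled by the inner
    dimension and an exp(2*alpha*step) factor, so each node's self-message
    progressively dominates. This freezes the messages as iterations
    proceed, which is what makes the damped Tanimoto loop converge (the raw
    similarity grows with vector norm and would otherwise diverge)."""
    n = sim.shape[0]
    if n < 2:
        return
    off = sim.copy()
    np.fill_diagonal(off, np.nan)
    # z-score the off-diagonal so the layer keeps a meaningful zero (the raw
    # similarity of sparse rows is positively offset), then let the
    # self-similarity diagonal grow
    mu = np.nanmean(off)
    sd = np.nanstd(off)
    if sd > 0:
        diag = np.diag(sim).copy()
        sim -= mu
        sim /= sd
        np.fill_diagonal(sim, diag)
    off = sim.copy()
    np.fill_diagonal(off, np.nan)
    row_std = np.nanstd(off, axis=1)
    np.fill_diagonal(sim, row_std * inner_dim * np.exp(2.0 * alpha * step))


def panda_infer(
    motif: pd.DataFrame,
    ppi: pd.DataFrame,
    coexpr: pd.DataFrame,
    cfg: PandaConfig | None = None,
    cell_type: str = "",
    condition: str = "",
) -> Grn:
    """Run the damped message-passing loop on name-aligned priors.

    ``motif`` is TF x gene, ``ppi`` TF x TF (symmetric), ``coexpr`` gene x
    gene. Genes in the coexpression network but absent from the motif prior
    are retained with all-zero prior columns; TFs of the motif prior missing
    from the PPI index are an error (they carry no cooperativity evidence).
    Returns the final network with the change statistic's convergence flag
    and the co-evolved TF-TF layer in ``ppi_out``."""
    cfg = cfg or PandaConfig()
    tfs = list(motif.index)
    if list(ppi.index) != tfs or list(ppi.columns) != tfs:
        raise ValueError("ppi must be indexed by the motif TFs in the same order")
    genes = list(coexpr.index)
    if list(coexpr.columns) != genes:
        raise ValueError("coexpr must be square with matching index/columns")
    extra = [g for g in motif.columns if g not in set(genes)]
    if extra:
        raise ValueError(f"motif genes missing from coexpression: {extra[:5]}")
    motif_full = motif.reindex(columns=genes).fillna(0.0)

    W = normalize_prior(motif_full.values)
    P = normalize_prior(ppi.values)
    C = normalize_prior(coexpr.values)

    iterations = 0
    converged = False
    for it in range(1, cfg.max_iter + 1):
        if cfg.alpha == 0.0:
            iterations = 0
            converged = True
            break
        R = continuous_tanimoto(P, W.T)  # TF x gene, inner dim TFs
        A = continuous_tanimoto(W, C)  # TF x gene, inner dim genes
        W_new = (1 - cfg.alpha) * W + cfg.alpha * 0.5 * (R + A)
        if not np.all(np.isfinite(W_new)):
            raise FloatingPointError(f"non-finite network update at iteration {it}")
        P_sim = continuous_tanimoto(W_new, W_new)
        _stabilize_diagonal(P_sim, len(genes), cfg.alpha, it)
        P = (1 - cfg.alpha) * P + cfg.alpha * P_sim
        C_sim = continuous_tanimoto(W_new.T, W_new.T)
        _stabilize_diagonal(C_sim, len(tfs), cfg.alpha, it)
        C = (1 - cfg.alpha) * C + cfg.alpha * C_sim
        delta = np.abs(W_new - W).mean()
        W = W_new
        iterations = it
        if delta < cfg.tol:
            converged = True
            break
    return Grn(
        tfs=tfs,
        genes=genes,
        weights=W,
        cell_type=cell_type,
        condition=condition,
        iterations_run=iterations,
        converged=converged,
        ppi_out=pd.DataFrame(P, index=tfs, columns=tfs),
    )
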