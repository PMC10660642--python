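"""Bipartite community structure and differential communities.

Community detection works on the positive edges of an inferred regulatory
network. The objective for a single network is Barber's bipartite
modularity,

    Q = (1/m) * sum_ij [A_ij - k_i * d_j / m] * delta(c_i, c_j),

summed over TF x gene pairs, where m is the total edge weight and k, d are
TF and gene strengths. For two condition networks, the differential
modularity scores each case edge against a null derived from the control
network,

    D_ij = w_case_ij / m_case - k_ctrl_i * d_ctrl_j / m_ctrl^2,

and the same partition optimizer maximizes the within-community sum of D.
The optimizer is a deterministic, seeded multi-restart scheme: alternating
TF/gene label sweeps (each node moves to the community with the highest
gain, ties resolved toward the lowest community id, with a fresh singleton
community whenever every move has negative gain) interleaved with greedy
community merges, iterated to a fixed point; the best-scoring restart wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn import Grn

__all__ = [
    "BipartitePartition",
    "DifferentialCommunityResult",
    "positive_projection",
    "barber_modularity",
    "condor_partition",
    "alpaca_differential",
    "jaccard",
    "focal_community_similarity",
]

Node = tuple[str, str]  # (role, name); role in {"tf", "gene"}


@dataclass
class BipartitePartition:
    assignment: dict[Node, int]
    modularity: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, community: int) -> set[Node]:
        return {n for n, c in self.assignment.items() if c == community}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"node": name, "role": role, "community": c}
                for (role, name), c in sorted(self.assignment.items())
            ]
        )


@dataclass
class DifferentialCommunityResult:
    assignment: dict[Node, int]
    node_scores: dict[Node, float]
    focal_members: set[Node]
    differential_modularity: float
    baseline: BipartitePartition | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node": name,
                    "role": role,
                    "community": c,
                    "score": self.node_scores[(role, name)],
                    "in_focal_community": (role, name) in self.focal_members,
                }
                for (role, name), c in sorted(self.assignment.items())
            ]
        )


def positive_projection(grn: Grn) -> pd.DataFrame:
    """Edge list (tf, gene, weight) of the strictly positive network edges.

    Nodes left without any positive edge are dropped (reported via a
    warning); an all-nonpositive network is an error."""
    ti, gi = np.nonzero(grn.weights > 0)
    if ti.size == 0:
        raise ValueError("network has no positive edges; nothing to partition")
    edges = pd.DataFrame(
        {
            "tf": np.asarray(grn.tfs)[ti],
            "gene": np.asarray(grn.genes)[gi],
            "weight": grn.weights[ti, gi],
        }
    )
    dropped_tfs = sorted(set(grn.tfs) - set(edges["tf"]))
    dropped_genes = sorted(set(grn.genes) - set(edges["gene"]))
    if dropped_tfs or dropped_genes:
        warnings.warn(
            f"dropped isolated nodes: {len(dropped_tfs)} TFs, {len(dropped_genes)} genes"
        )
    return edges


def _edge_matrix(edges: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    tfs = sorted(set(edges["tf"]))
    genes = sorted(set(edges["gene"]))
    tpos = {t: i for i, t in enumerate(tfs)}
    gpos = {g: j for j, g in enumerate(genes)}
    A = np.zeros((len(tfs), len(genes)))
    A[[tpos[t] for t in edges["tf"]], [gpos[g] for g in edges["gene"]]] = edges[
        "weight"
    ].values
    return A, tfs, genes


def barber_modularity(
    assignment: dict[Node, int], edges: pd.DataFrame
) -> float:
    """Barber bipartite modularity of a partition over a weighted edge list."""
    A, tfs, genes = _edge_matrix(edges)
    for role, names in (("tf", tfs), ("gene", genes)):
        missing = [n for n in names if (role, n) not in assignment]
        if missing:
            raise ValueError(f"unassigned {role} nodes: {missing[:5]}")
    m = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    B = (A - np.outer(k, d) / m) / m
    ct = np.array([assignment[("tf", t)] for t in tfs])
    cg = np.array([assignment[("gene", g)] for g in genes])
    return float((B * (ct[:, None] == cg[None, :])).sum())


def _sweep_optimize(
    B: np.ndarray,
    seed: int,
    edge_mask: np.ndarray | None = None,
    n_restarts: int = 8,
    max_rounds: int = 60,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Maximize sum_ij B_ij delta(ct_i, cg_j) over joint TF/gene partitions.

    ``edge_mask`` marks actual network edges; it only affects the final
    tie-resolution pass (score-neutral edges keep their endpoints together,
    score-neutral non-edges do not)."""
    nT, nG = B.shape
    if edge_mask is None:
        edge_mask = B > 0
    rng = np.random.default_rng(seed)

    def score(ct, cg):
        return float((B * (ct[:, None] == cg[None, :])).sum())

    def relabel(ct, cg):
        labels = np.concatenate([ct, cg])
        uniq = {c: i for i, c in enumerate(pd.unique(labels))}
        return (
            np.array([uniq[c] for c in ct]),
            np.array([uniq[c] for c in cg]),
        )

    def indicator(labels, K):
        M = np.zeros((len(labels), K))
        M[np.arange(len(labels)), labels] = 1.0
        return M

    def sweeps(ct, cg):
        for _ in range(max_rounds):
            changed = False
            ct, cg = relabel(ct, cg)
            K = max(ct.max(initial=-1), cg.max(initial=-1)) + 1
            # genes move given TF labels (strict improvement only; a gene
            # with all-negative attachments is isolated)
            gains = indicator(ct, K).T @ B  # K x nG
            best = gains.argmax(axis=0)
            bestval = gains[best, np.arange(nG)]
            cur = gains[cg, np.arange(nG)]
            new_cg = cg.copy()
            fresh = K
            for j in range(nG):
                if bestval[j] > max(cur[j], 0.0) + 1e-12:
                    new_cg[j] = best[j]
                elif cur[j] < -1e-12:
                    new_cg[j] = fresh
                    fresh += 1
            if not np.array_equal(new_cg, cg):
                changed = True
            cg = new_cg
            ct, cg = relabel(ct, cg)
            K = max(ct.max(initial=-1), cg.max(initial=-1)) + 1
            # TFs move given gene labels
            gains = B @ indicator(cg, K)  # nT x K
            best = gains.argmax(axis=1)
            bestval = gains[np.arange(nT), best]
            cur = gains[np.arange(nT), ct]
            new_ct = ct.copy()
            fresh = K
            for i in range(nT):
                if bestval[i] > max(cur[i], 0.0) + 1e-12:
                    new_ct[i] = best[i]
                elif cur[i] < -1e-12:
                    new_ct[i] = fresh
                    fresh += 1
            if not np.array_equal(new_ct, ct):
                changed = True
            ct = new_ct
            if not changed:
                break
        return relabel(ct, cg)

    def split_components(ct, cg):
        # among score-tied optima prefer the finest partition: break each
        # community into connected components of its positive-B subgraph
        # (cross-component pairs have B <= 0, so this never lowers the score)
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        ct, cg = relabel(ct, cg)
        K = max(ct.max(initial=-1), cg.max(initial=-1)) + 1
        new_ct, new_cg = ct.copy(), cg.copy()
        next_label = 0
        for c in range(K):
            t_idx = np.where(ct == c)[0]
            g_idx = np.where(cg == c)[0]
            n = len(t_idx) + len(g_idx)
            if n == 0:
                continue
            if len(t_idx) and len(g_idx):
                sub_B = B[np.ix_(t_idx, g_idx)]
                sub_E = edge_mask[np.ix_(t_idx, g_idx)]
                # positive contributions connect; score-neutral real edges
                # also connect (a lone zero-modularity edge is one community)
                sub = (sub_B > 0) | (sub_E & (sub_B >= 0))
            else:
                sub = None
            rows, cols = np.nonzero(sub) if sub is not None else ([], [])
            adj = coo_matrix(
                (np.ones(len(rows)), (rows, np.asarray(cols, int) + len(t_idx))),
                shape=(n, n),
            )
            n_comp, labels = connected_components(adj, directed=False)
            for i, t in enumerate(t_idx):
                new_ct[t] = next_label + labels[i]
            for j, g in enumerate(g_idx):
                new_cg[g] = next_label + labels[len(t_idx) + j]
            next_label += n_comp
        return relabel(new_ct, new_cg)

    def merges(ct, cg):
        while True:
            ct, cg = relabel(ct, cg)
            K = max(ct.max(initial=-1), cg.max(initial=-1)) + 1
            if K < 2:
                return ct, cg
            S = indicator(ct, K).T @ B @ indicator(cg, K)  # K x K inter-community
            gain = S + S.T
            np.fill_diagonal(gain, -np.inf)
            a, b = np.unravel_index(np.argmax(gain), gain.shape)
            if gain[a, b] <= 1e-12:
                return ct, cg
            lo, hi = min(a, b), max(a, b)
            ct = np.where(ct == hi, lo, ct)
            cg = np.where(cg == hi, lo, cg)

    best_ct = best_cg = None
    best_score = -np.inf
    for r in range(n_restarts):
        if r == 0:
            # singleton TFs; each gene starts with its strongest TF
            ct = np.arange(nT)
            cg = B.argmax(axis=0).copy()
        elif r == 1:
            # every node isolated; structure grows bottom-up
            ct = np.arange(nT)
            cg = nT + np.arange(nG)
        else:
            K = int(rng.integers(2, max(3, min(10, nT + 1))))
            ct = rng.integers(0, K, size=nT)
            cg = rng.integers(0, K, size=nG)
        prev = -np.inf
        for _ in range(20):
            ct, cg = sweeps(ct, cg)
            ct, cg = merges(ct, cg)
            s = score(ct, cg)
            if s <= prev + 1e-12:
                break
            prev = s
        ct, cg = split_components(ct, cg)
        s = score(ct, cg)
        if s > best_score + 1e-12:
            best_score = s
            best_ct, best_cg = relabel(ct, cg)
    return best_ct, best_cg, best_score


def condor_partition(edges: pd.DataFrame, seed: int = 0) -> BipartitePartition:
    """Barber-modularity-maximizing bipartite partition of an edge list."""
    if len(edges) == 0:
        raise ValueError("empty edge list")
    A, tfs, genes = _edge_matrix(edges)
    m = A.sum()
    if m <= 0:
        raise ValueError("total edge weight must be positive")
    B = (A - np.outer(A.sum(axis=1), A.sum(axis=0)) / m) / m
    ct, cg, q = _sweep_optimize(B, seed, edge_mask=A > 0)
    assignment: dict[Node, int] = {}
    for i, t in enumerate(tfs):
        assignment[("tf", t)] = int(ct[i])
    for j, g in enumerate(genes):
        assignment[("gene", g)] = int(cg[j])
    return BipartitePartition(assignment=assignment, modularity=q, seed=seed)


def alpaca_differential(
    case_edges: pd.DataFrame,
    ctrl_edges: pd.DataFrame,
    focal_tf: str,
    seed: int = 0,
    baseline: bool = True,
) -> DifferentialCommunityResult:
    """Differential community structure of the case network against the
    control-derived null.

    The differential modularity matrix is built over the case network's
    nodes; nodes absent from the control network contribute a zero null
    term. The partition maximizing the within-community sum of D is found by
    the same optimizer as :func:`condor_partition`."""
    A_case, tfs, genes = _edge_matrix(case_edges)
    if focal_tf not in set(tfs):
        raise ValueError(f"focal TF {focal_tf!r} absent from the case network")
    m_case = A_case.sum()
    A_ctrl, ctfs, cgenes = _edge_matrix(ctrl_edges)
    m_ctrl = A_ctrl.sum()
    k_ctrl = dict(zip(ctfs, A_ctrl.sum(axis=1)))
    d_ctrl = dict(zip(cgenes, A_ctrl.sum(axis=0)))
    k = np.array([k_ctrl.get(t, 0.0) for t in tfs])
    d = np.array([d_ctrl.get(g, 0.0) for g in genes])
    D = A_case / m_case - np.outer(k, d) / (m_ctrl**2)
    ct, cg, dq = _sweep_optimize(D, seed, edge_mask=A_case > 0)
    assignment: dict[Node, int] = {}
    for i, t in enumerate(tfs):
        assignment[("tf", t)] = int(ct[i])
    for j, g in enumerate(genes):
        assignment[("gene", g)] = int(cg[j])
    within = ct[:, None] == cg[None, :]
    node_scores: dict[Node, float] = {}
    for i, t in enumerate(tfs):
        node_scores[("tf", t)] = float((D[i] * within[i]).sum())
    for j, g in enumerate(genes):
        node_scores[("gene", g)] = float((D[:, j] * within[:, j]).sum())
    focal_c = assignment[("tf", focal_tf)]
    focal_members = {n for n, c in assignment.items() if c == focal_c}
    base = condor_partition(ctrl_edges, seed=seed) if baseline else None
    return DifferentialCommunityResult(
        assignment=assignment,
        node_scores=node_scores,
        focal_members=focal_members,
        differential_modularity=dq,
        baseline=base,
    )


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b|; two empty sets score 0 (with a warning)."""
    if not a and not b:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(a | b)


def focal_community_similarity(
    results: dict[str, DifferentialCommunityResult],
    genes_only: bool = False,
) -> pd.DataFrame:
    """Cell type x cell type Jaccard matrix of focal-TF community members.

    By default both TF and gene nodes enter the comparison; ``genes_only``
    restricts to gene nodes."""
    if len(results) < 2:
        raise ValueError("need >= 2 cell types to compare")
    cts = list(results)
    sets = {}
    for ct, res in results.items():
        mem = res.focal_members
        if genes_only:
            mem = {n for n in mem if n[0] == "gene"}
        sets[ct] = mem
    M = np.ones((len(cts), len(cts)))
    for i in range(len(cts)):
        for j in range(i + 1, len(cts)):
            ji = jaccard(sets[cts[i]], sets[cts[j]])
            M[i, j] = M[j, i] = ji
    return pd.DataFrame(M, index=cts, columns=cts)
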