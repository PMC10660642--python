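"""Bipartite modularity, partition optimization vs. exhaustive enumeration,
and differential-community behaviour on planted structure."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_bipartite_edges, set_partitions
from grnrewire.communities import (
    alpaca_differential,
    barber_modularity,
    condor_partition,
    focal_community_similarity,
    jaccard,
    positive_projection,
)
from grnrewire.grn import Grn


def _edges(rows):
    return pd.DataFrame(rows, columns=["tf", "gene", "weight"])


class TestPositiveProjection:
    def test_all_negative_errors(self):
        grn = Grn(tfs=["t0"], genes=["g0"], weights=np.array([[-1.0]]))
        with pytest.raises(ValueError):
            positive_projection(grn)

    def test_strict_positivity(self):
        grn = Grn(
            tfs=["t0"], genes=["g0", "g1", "g2"], weights=np.array([[-1.0, 0.0, 2.0]])
        )
        with pytest.warns(UserWarning, match="isolated"):
            edges = positive_projection(grn)
        assert len(edges) == 1 and edges.iloc[0]["weight"] == 2.0

    def test_count_matches_positive_entries(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(5, 12))
        grn = Grn(
            tfs=[f"t{i}" for i in range(5)],
            genes=[f"g{j}" for j in range(12)],
            weights=W,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edges = positive_projection(grn)
        assert len(edges) == int((W > 0).sum())


class TestBarberModularity:
    def test_single_community_zero(self):
        edges = _edges([("t0", "g0", 1.0), ("t0", "g1", 2.0), ("t1", "g1", 1.0)])
        asg = {("tf", "t0"): 0, ("tf", "t1"): 0, ("gene", "g0"): 0, ("gene", "g1"): 0}
        assert barber_modularity(asg, edges) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_unit_edges(self):
        edges = _edges([("t0", "g0", 1.0), ("t1", "g1", 1.0)])
        asg = {("tf", "t0"): 0, ("gene", "g0"): 0, ("tf", "t1"): 1, ("gene", "g1"): 1}
        assert barber_modularity(asg, edges) == pytest.approx(0.5)

    def test_unassigned_node_errors(self):
        edges = _edges([("t0", "g0", 1.0)])
        with pytest.raises(ValueError, match="unassigned"):
            barber_modularity({("tf", "t0"): 0}, edges)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(1)
        edges = random_bipartite_edges(rng, 4, 6)
        asg = {("tf", f"t{i}"): i % 2 for i in range(4)}
        asg.update({("gene", f"g{j}"): j % 2 for j in range(6)})
        asg = {k: v for k, v in asg.items()
               if k[1] in set(edges["tf"]) | set(edges["gene"])}
        q = barber_modularity(asg, edges)
        assert -1.0 <= q <= 1.0


class TestCondorPartition:
    def test_single_edge(self):
        part = condor_partition(_edges([("t0", "g0", 1.0)]), seed=0)
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_two_bicliques_recovered(self):
        rows = []
        for t in range(2):
            for g in range(3):
                rows.append((f"at{t}", f"ag{g}", 1.0))
                rows.append((f"bt{t}", f"bg{g}", 1.0))
        part = condor_partition(_edges(rows), seed=1)
        a_comms = {part.assignment[("tf", f"at{t}")] for t in range(2)}
        a_comms |= {part.assignment[("gene", f"ag{g}")] for g in range(3)}
        b_comms = {part.assignment[("tf", f"bt{t}")] for t in range(2)}
        b_comms |= {part.assignment[("gene", f"bg{g}")] for g in range(3)}
        assert len(a_comms) == 1 and len(b_comms) == 1 and a_comms != b_comms
        assert part.modularity == pytest.approx(0.5)

    def test_empty_edge_list(self):
        with pytest.raises(ValueError):
            condor_partition(_edges([]), seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        edges = random_bipartite_edges(rng, 6, 10)
        p1 = condor_partition(edges, seed=5)
        p2 = condor_partition(edges, seed=5)
        assert p1.assignment == p2.assignment
        assert p1.modularity == p2.modularity

    @pytest.mark.parametrize("trial", range(12))
    def test_attains_enumeration_optimum_small_graphs(self, trial):
        rng = np.random.default_rng(trial)
        nT = int(rng.integers(2, 4))
        nG = int(rng.integers(2, 7 - nT))
        edges = random_bipartite_edges(rng, nT, nG, p=0.6)
        if len(edges) == 0:
            pytest.skip("no edges drawn")
        part = condor_partition(edges, seed=trial)
        nodes = [("tf", t) for t in sorted(set(edges["tf"]))] + [
            ("gene", g) for g in sorted(set(edges["gene"]))
        ]
        best = max(barber_modularity(asg, edges) for asg in set_partitions(nodes))
        assert part.modularity == pytest.approx(best, abs=1e-9)

    def test_sbm_recovery_sample(self):
        from sklearn.metrics import adjusted_rand_score

        succ = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            nT, nG, K = 20, 40, 4
            ct_true = np.repeat(np.arange(K), nT // K)
            cg_true = np.repeat(np.arange(K), nG // K)
            P = np.where(ct_true[:, None] == cg_true[None, :], 0.9, 0.05)
            A = (rng.random((nT, nG)) < P).astype(float)
            rows = [
                (f"t{i:02d}", f"g{j:02d}", 1.0)
                for i in range(nT)
                for j in range(nG)
                if A[i, j]
            ]
            part = condor_partition(_edges(rows), seed=seed)
            lt, lf = [], []
            for i in range(nT):
                key = ("tf", f"t{i:02d}")
                if key in part.assignment:
                    lt.append(ct_true[i])
                    lf.append(part.assignment[key])
            for j in range(nG):
                key = ("gene", f"g{j:02d}")
                if key in part.assignment:
                    lt.append(cg_true[j])
                    lf.append(part.assignment[key])
            succ += adjusted_rand_score(lt, lf) >= 0.9
        assert succ >= 9


class TestAlpacaDifferential:
    def _background(self, seed, nT=10, nG=20, p=0.3):
        rng = np.random.default_rng(seed)
        A = (rng.random((nT, nG)) < p) * 1.0
        rows = [
            (f"t{i}", f"g{j}", A[i, j])
            for i in range(nT)
            for j in range(nG)
            if A[i, j] > 0
        ]
        return _edges(rows)

    def test_focal_missing_errors(self):
        edges = self._background(0)
        with pytest.raises(ValueError, match="focal"):
            alpaca_differential(edges, edges, "not_there", seed=0)

    def test_scale_invariance(self):
        case = self._background(1)
        ctrl = self._background(2)
        r1 = alpaca_differential(case, ctrl, "t0", seed=3, baseline=False)
        case2 = case.copy()
        case2["weight"] *= 7.0
        r2 = alpaca_differential(case2, ctrl, "t0", seed=3, baseline=False)
        assert r1.assignment == r2.assignment
        assert r1.differential_modularity == pytest.approx(r2.differential_modularity)
        ctrl2 = ctrl.copy()
        ctrl2["weight"] *= 0.25
        r3 = alpaca_differential(case, ctrl2, "t0", seed=3, baseline=False)
        assert r1.assignment == r3.assignment

    def test_planted_new_module_recovered(self):
        succ = 0
        for seed in range(10):
            bg = self._background(2000 + seed)
            extra = [(f"nt{i}", f"ng{j}", 2.0) for i in range(4) for j in range(8)]
            case = pd.concat([bg, _edges(extra)], ignore_index=True)
            res = alpaca_differential(case, bg, "t0", seed=seed, baseline=False)
            truth_nodes = {("tf", f"nt{i}") for i in range(4)} | {
                ("gene", f"ng{j}") for j in range(8)
            }
            comms = {}
            for n, c in res.assignment.items():
                comms.setdefault(c, set()).add(n)
            best = max(jaccard(m, truth_nodes) for m in comms.values())
            succ += best >= 0.8
        assert succ >= 9

    def test_node_scores_sum_to_objective(self):
        case = self._background(5)
        ctrl = self._background(6)
        res = alpaca_differential(case, ctrl, "t0", seed=0, baseline=False)
        # TF-side scores partition the objective
        tf_total = sum(v for (role, _), v in res.node_scores.items() if role == "tf")
        assert tf_total == pytest.approx(res.differential_modularity, abs=1e-9)
        assert ("tf", "t0") in res.focal_members


class TestJaccard:
    def test_trivial_values(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_empty_sets_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert jaccard(set(), set()) == 0.0


class TestFocalSimilarityMatrix:
    def _result(self, members):
        from grnrewire.communities import DifferentialCommunityResult

        return DifferentialCommunityResult(
            assignment={n: 0 for n in members},
            node_scores={n: 0.0 for n in members},
            focal_members=set(members),
            differential_modularity=0.0,
        )

    def test_matrix_matches_pairwise_jaccard(self):
        results = {
            "a": self._result({("tf", "f"), ("gene", "x"), ("gene", "y")}),
            "b": self._result({("tf", "f"), ("gene", "y"), ("gene", "z")}),
            "c": self._result({("tf", "f"), ("gene", "x"), ("gene", "y")}),
        }
        M = focal_community_similarity(results)
        assert M.loc["a", "c"] == 1.0
        assert M.loc["a", "b"] == pytest.approx(0.5)
        np.testing.assert_array_equal(M.values, M.values.T)
        np.testing.assert_array_equal(np.diag(M.values), 1.0)

    def test_genes_only_flag(self):
        results = {
            "a": self._result({("tf", "f"), ("gene", "x")}),
            "b": self._result({("tf", "f"), ("gene", "y")}),
        }
        M_all = focal_community_similarity(results)
        M_g = focal_community_similarity(results, genes_only=True)
        assert M_all.loc["a", "b"] == pytest.approx(1 / 3)
        assert M_g.loc["a", "b"] == 0.0

    def test_needs_two_cell_types(self):
        with pytest.raises(ValueError):
            focal_community_similarity({"a": self._result({("tf", "f")})})
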