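import itertools
import math

import numpy as np
import pytest

from intercom.compatibility import (
    SignedPath,
    compatibility_test,
    functional_receptors,
    interface_tfs,
    signed_paths,
    assess_compatibility,
)
from intercom.errors import ValidationError
from intercom.markov_signaling import HotspotSet
from intercom.tf_core import PreservedTFSet

from conftest import make_matrix, make_network, make_profile, make_regulon, random_network


def enumerate_upper_tail(N, K, n, k):
    """Exhaustive oracle: fraction of size-n subsets of N items (K of them
    'active') whose overlap with the active set is >= k."""
    items = range(N)
    active = set(range(K))
    total = hits = 0
    for subset in itertools.combinations(items, n):
        total += 1
        if len(active.intersection(subset)) >= k:
            hits += 1
    return hits / total


def dfs_paths_oracle(edges, source, targets, max_len):
    """Independent recursive enumeration of simple signed paths."""
    adj = {}
    for s, t, g in edges:
        adj.setdefault(s, []).append((t, g))
    out = []

    def walk(node, path, sign):
        if len(path) - 1 > max_len:
            return
        if node in targets and len(path) > 1:
            out.append((tuple(path), sign))
        if len(path) - 1 == max_len:
            return
        for nxt, g in adj.get(node, []):
            if nxt not in path:
                walk(nxt, path + [nxt], sign * g)

    walk(source, [source], 1)
    return set(out)


class TestInterfaceTFs:
    def net(self):
        return make_network([("R", "I", 1), ("I", "T1", 1)])

    def test_only_grounded_tf_kept(self):
        regs = {"T1": make_regulon("T1", [("x", 1)]), "T2": make_regulon("T2", [("y", 1)])}
        preserved = PreservedTFSet("p", ["T1", "T2"], 0.9)
        assert interface_tfs(self.net(), regs, preserved) == {"T1"}

    def test_none_preserved_errors(self):
        with pytest.raises(ValidationError):
            interface_tfs(self.net(), {"T1": make_regulon("T1", [("x", 1)])},
                          PreservedTFSet("p", [], 0.9))

    def test_isolated_tf_excluded(self):
        # T2 has a regulon but no incoming signaling edge
        net = make_network([("R", "I", 1), ("I", "T1", 1), ("T2", "I", 1)])
        regs = {"T1": make_regulon("T1", [("x", 1)]), "T2": make_regulon("T2", [("y", 1)])}
        preserved = PreservedTFSet("p", ["T1", "T2"], 0.9)
        assert interface_tfs(net, regs, preserved) == {"T1"}


class TestSignedPaths:
    def test_chain_sign_product(self):
        net = make_network([("R", "I", 1), ("I", "T", -1)])
        paths = signed_paths(net, "R", {"T"})
        assert paths == [SignedPath(("R", "I", "T"), -1)]
        assert paths[0].length == 2

    def test_parallel_paths_both_returned(self):
        net = make_network([("R", "A", 1), ("A", "T", 1), ("R", "B", 1), ("B", "T", -1)])
        signs = {p.sign for p in signed_paths(net, "R", {"T"})}
        assert signs == {1, -1}

    def test_max_len_exclusion(self):
        net = make_network([(f"n{i}", f"n{i+1}", 1) for i in range(6)])
        assert signed_paths(net, "n0", {"n6"}, max_path_len=5) == []
        assert len(signed_paths(net, "n0", {"n6"}, max_path_len=6)) == 1

    def test_cap_limits_enumeration(self, caplog):
        # complete-ish DAG explodes combinatorially
        rng = np.random.default_rng(0)
        net = random_network(rng, 8, 0.9)
        out = signed_paths(net, net.nodes[0], set(net.nodes[1:]), max_path_len=7, cap=50)
        assert len(out) == 50

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_dfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        net = random_network(rng, n, 0.35)
        source = net.nodes[0]
        targets = set(rng.choice(net.nodes[1:], size=min(3, n - 1), replace=False))
        max_len = int(rng.integers(1, 6))
        got = {(p.nodes, p.sign) for p in signed_paths(net, source, targets, max_path_len=max_len)}
        edges = [(e.source, e.target, e.sign) for e in net.edges]
        assert got == dfs_paths_oracle(edges, source, targets, max_len)


class TestCompatibilityTest:
    def test_worked_case_exact(self):
        # N=5, K=3, n=3, k=3 -> C(3,3)C(2,0)/C(5,3) = 1/10
        reg = make_regulon("T", [(f"t{i}", 1) for i in range(5)])
        binary = {"t0": 1, "t1": 1, "t2": 1, "t3": -1, "t4": -1}
        # choose a state/sign so exactly t0..t2 are predicted active
        reg = make_regulon("T", [("t0", 1), ("t1", 1), ("t2", 1), ("t3", -1), ("t4", -1)])
        res = compatibility_test(1, 1, reg, binary)
        assert (res.N, res.K, res.n, res.k) == (5, 3, 3, 3)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert not res.compatible  # 0.1 >= alpha 0.05

    def test_nothing_predicted_active(self):
        reg = make_regulon("T", [("t0", -1), ("t1", -1)])
        res = compatibility_test(1, 1, reg, {"t0": 1, "t1": 1})
        assert (res.n, res.k) == (0, 0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.compatible

    def test_single_target_degenerate(self):
        reg = make_regulon("T", [("t0", 1)])
        res = compatibility_test(1, 1, reg, {"t0": 1})
        assert (res.N, res.K, res.n, res.k) == (1, 1, 1, 1)
        assert res.p_value == pytest.approx(1.0)
        assert not res.compatible

    def test_untestable_regulon(self):
        reg = make_regulon("T", [("t0", 1)])
        res = compatibility_test(1, 1, reg, {})
        assert res.p_value == 1.0
        assert not res.compatible
        assert res.reason == "no measured regulon target"

    def test_strong_agreement_is_compatible(self):
        targets = [(f"p{i}", 1) for i in range(5)] + [(f"m{i}", -1) for i in range(5)]
        reg = make_regulon("T", targets)
        binary = {f"p{i}": 1 for i in range(5)} | {f"m{i}": -1 for i in range(5)}
        res = compatibility_test(1, 1, reg, binary)
        assert (res.N, res.K, res.n, res.k) == (10, 5, 5, 5)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5), abs=1e-12)
        assert res.compatible

    def test_grid_against_enumeration_small(self):
        for N in range(1, 7):
            for K in range(N + 1):
                for n in range(N + 1):
                    reg = make_regulon("T", [(f"t{i}", 1) for i in range(N)])
                    binary = {f"t{i}": (1 if i < K else -1) for i in range(N)}
                    # engineer n predicted-active by sign choice per target
                    reg = make_regulon(
                        "T", [(f"t{i}", 1 if i < n else -1) for i in range(N)]
                    )
                    # with this construction k = |{i < min(n, K)}|
                    res = compatibility_test(1, 1, reg, binary)
                    assert res.k == min(n, K)
                    expected = enumerate_upper_tail(N, K, n, res.k)
                    assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_double_flip_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            N = int(rng.integers(1, 8))
            reg = make_regulon("T", [(f"t{i}", int(rng.choice([1, -1]))) for i in range(N)])
            binary = {f"t{i}": int(rng.choice([1, -1])) for i in range(N)}
            a = compatibility_test(1, 1, reg, binary)
            b = compatibility_test(-1, -1, reg, binary)
            assert (a.N, a.K, a.n, a.k, a.p_value) == (b.N, b.K, b.n, b.k, b.p_value)

    def test_alpha_monotonicity(self):
        reg = make_regulon("T", [(f"t{i}", 1 if i < 3 else -1) for i in range(8)])
        binary = {f"t{i}": (1 if i < 3 else -1) for i in range(8)}
        compatible_at = [
            alpha
            for alpha in (0.001, 0.01, 0.05, 0.2, 0.5)
            if compatibility_test(1, 1, reg, binary, alpha=alpha).compatible
        ]
        # once compatible, stays compatible at any larger alpha
        if compatible_at:
            assert compatible_at == [a for a in (0.001, 0.01, 0.05, 0.2, 0.5) if a >= compatible_at[0]]


def _functional_fixture(n_on: int):
    """Receptor->I->T chain where exactly n_on of 100 cells co-express
    receptor, TF, and an observed-active target.

    T's regulon mixes 5 activated targets (expressed) with 3 repressed ones
    (measured but silent), so the hypergeometric test has signal:
    p = 1/C(8,5) ~ 0.018 < 0.05.
    """
    n_cells = 100
    active = [f"x{i}" for i in range(5)]
    silent = [f"m{i}" for i in range(3)]
    genes = ["R", "I", "T", *active, *silent]
    counts = np.zeros((n_cells, len(genes)))
    counts[:n_on, 0] = 1  # receptor
    counts[:80, 1] = 1    # intermediate I
    counts[:80, 2] = 1    # TF
    for j in range(len(active)):
        counts[:80, 3 + j] = 1
    matrix = make_matrix(counts, genes)
    profile = make_profile(counts, genes)
    net = make_network([("R", "I", 1), ("I", "T", 1)])
    net.receptors = {"R"}
    net.interface_tfs = {"T"}
    regs = {
        "T": make_regulon(
            "T", [(g, 1) for g in active] + [(g, -1) for g in silent]
        )
    }
    hotspots = HotspotSet("pop", ["I"], 0.0)
    compat = assess_compatibility(net, hotspots, {"T"}, regs, profile)
    return net, hotspots, compat, matrix, profile, regs


class TestFunctionalReceptors:
    def test_retained_above_cofrac(self):
        net, hot, compat, matrix, profile, regs = _functional_fixture(n_on=8)
        out = functional_receptors(net, hot, compat, matrix, profile, regs, min_cofrac=0.05)
        assert out.receptors == ["R"]
        assert out.supporting["R"][0]["tf"] == "T"

    def test_dropped_below_cofrac(self):
        net, hot, compat, matrix, profile, regs = _functional_fixture(n_on=4)
        out = functional_receptors(net, hot, compat, matrix, profile, regs, min_cofrac=0.05)
        assert out.receptors == []

    def test_boundary_exactly_at_cofrac_retained(self):
        net, hot, compat, matrix, profile, regs = _functional_fixture(n_on=5)
        out = functional_receptors(net, hot, compat, matrix, profile, regs, min_cofrac=0.05)
        assert out.receptors == ["R"]

    def test_no_path_to_hotspot_dropped(self):
        net, _, compat, matrix, profile, regs = _functional_fixture(n_on=50)
        # hotspot set that the receptor cannot reach
        hot = HotspotSet("pop", ["T"], 0.0)
        compat = [c for c in compat]  # compat evidence names intermediate "I"
        out = functional_receptors(net, hot, compat, matrix, profile, regs, min_cofrac=0.05)
        assert out.receptors == []

    def test_min_cofrac_monotonicity(self):
        net, hot, compat, matrix, profile, regs = _functional_fixture(n_on=30)
        prev = None
        for cofrac in (0.0, 0.1, 0.2, 0.31, 0.9):
            kept = set(
                functional_receptors(
                    net, hot, compat, matrix, profile, regs, min_cofrac=cofrac
                ).receptors
            )
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestHotspotCompatibility:
    def test_planted_chain_found_compatible(self):
        net, hot, compat, *_ = _functional_fixture(n_on=50)
        assert any(c.compatible and c.intermediate == "I" and c.tf == "T" for c in compat)

    def test_compatible_requires_disagreeing_targets(self):
        # when every measured target is observed active, agreement is trivial
        n_cells = 10
        counts = np.ones((n_cells, 4))
        genes = ["R", "I", "T", "x"]
        profile = make_profile(counts, genes)
        net = make_network([("R", "I", 1), ("I", "T", 1)])
        regs = {"T": make_regulon("T", [("x", 1)])}
        compat = assess_compatibility(
            net, HotspotSet("pop", ["I"], 0.0), {"T"}, regs, profile
        )
        assert all(not c.compatible for c in compat)
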