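"""Shared builders for small in-memory fixtures."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from intercom.expression import ExpressionMatrix, profile_matrix
from intercom.knowledge_base import Regulon, SignalingNetwork, SignedEdge


def make_matrix(counts, genes, cells=None) -> ExpressionMatrix:
    counts = np.asarray(counts, dtype=float)
    if cells is None:
        cells = [f"c{i}" for i in range(counts.shape[0])]
    return ExpressionMatrix(sp.csr_matrix(counts), list(cells), list(genes))


def make_profile(counts, genes, population="pop"):
    return profile_matrix(make_matrix(counts, genes), population)


def make_network(edges) -> SignalingNetwork:
    """edges: iterable of (source, target, sign)."""
    signed = [SignedEdge(s, t, g) for s, t, g in edges]
    nodes, seen = [], set()
    for e in signed:
        for n in (e.source, e.target):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
    return SignalingNetwork(nodes=nodes, edges=signed)


def make_regulon(tf, targets) -> Regulon:
    """targets: iterable of (gene, sign)."""
    return Regulon(tf, [(g, s) for g, s in targets])


def random_network(rng: np.random.Generator, n_nodes: int, p_edge: float) -> SignalingNetwork:
    """Random directed signed graph without self-loops; every node kept in the
    node list even when isolated (it becomes a dangling uniform row)."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p_edge:
                edges.append(SignedEdge(names[i], names[j], 1 if rng.random() < 0.5 else -1))
    return SignalingNetwork(nodes=names, edges=edges)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
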