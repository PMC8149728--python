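"""Expression-weighted Markov chain over the signaling network.

Signal traversal is modeled as a finite discrete Markov chain whose transition
probabilities favour highly expressed target nodes; the stationary
distribution, obtained by power iteration, ranks nodes as signaling hotspots.
Edge signs play no role here (a traversal probability cannot be negative);
they enter only in downstream compatibility testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError
from .expression import PopulationProfile
from .knowledge_base import SignalingNetwork

logger = logging.getLogger(__name__)

#: floor added to every node weight so unexpressed genes keep nonzero mass
WEIGHT_EPSILON = 1e-6


@dataclass
class TransitionMatrix:
    node_order: list[str]
    P: np.ndarray  # row-stochastic
    damping: float

    def validate(self, atol: float = 1e-12) -> None:
        if np.any(self.P < 0):
            raise ValueError("transition matrix has negative entries")
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=atol):
            raise ValueError(f"rows not stochastic, max deviation {np.abs(rows - 1).max():.2e}")


@dataclass
class StationaryDistribution:
    node_order: list[str]
    pi: np.ndarray
    iterations: int
    residual: float  # final L1 change

    def probability(self, node: str) -> float:
        return float(self.pi[self.node_order.index(node)])


@dataclass
class HotspotSet:
    population: str
    intermediates: list[str]  # sorted by pi descending, ties by symbol
    quantile_cut: float


def node_weights(
    profile: PopulationProfile,
    nodes: list[str],
    mode: str = "fraction",
    epsilon: float = WEIGHT_EPSILON,
) -> np.ndarray:
    """Per-node traversal weights: expressed-cell fraction (or mean expression
    over expressing cells with ``mode='mean'``) plus a small epsilon.

    Genes absent from the matrix get weight epsilon.
    """
    if mode == "fraction":
        base = [profile.fraction(n, default=0.0) for n in nodes]
    elif mode == "mean":
        base = [profile.mean(n, default=0.0) for n in nodes]
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return np.asarray(base, dtype=float) + epsilon


def build_transition_matrix(
    network: SignalingNetwork,
    weights: np.ndarray,
    damping: float = 0.0,
) -> TransitionMatrix:
    """Build the row-stochastic state-transition matrix.

    For node i with out-neighbours N(i):
    P[i,j] = (1-damping) * w(j) / sum_{k in N(i)} w(k) + damping/n  for j in N(i),
    and damping/n otherwise.  Dangling nodes (no out-edges) get a uniform row.
    """
    nodes = network.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("empty signaling network")
    index = {g: i for i, g in enumerate(nodes)}
    P = np.full((n, n), damping / n, dtype=float)
    out: dict[int, list[int]] = {}
    for e in network.edges:
        out.setdefault(index[e.source], []).append(index[e.target])
    for i in range(n):
        succ = out.get(i)
        if not succ:
            P[i, :] = 1.0 / n
            continue
        w = weights[succ]
        total = w.sum()
        if total <= 0:
            raise RuntimeError("zero total weight on a transition row")
        P[i, succ] += (1.0 - damping) * w / total
    return TransitionMatrix(node_order=list(nodes), P=P, damping=damping)


def stationary_distribution(
    T: TransitionMatrix,
    tol: float = 1e-10,
    max_iter: int = 10000,
    start: np.ndarray | None = None,
) -> StationaryDistribution:
    """Evolve the chain by power iteration until the L1 change falls below tol.

    Raises :class:`ConvergenceError` (carrying the last iterate) when the
    chain does not converge, as happens for periodic chains without damping.
    """
    n = T.P.shape[0]
    pi = np.full(n, 1.0 / n) if start is None else np.asarray(start, dtype=float)
    residual = np.inf
    for it in range(1, max_iter + 1):
        nxt = pi @ T.P
        residual = float(np.abs(nxt - pi).sum())
        pi = nxt
        if residual <= tol:
            pi = pi / pi.sum()
            return StationaryDistribution(
                node_order=list(T.node_order), pi=pi, iterations=it, residual=residual
            )
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e}); consider damping > 0",
        last_iterate=pi,
        iterations=max_iter,
        residual=residual,
    )


def select_intermediates(
    dist: StationaryDistribution,
    quantile: float = 0.90,
    population: str = "",
) -> HotspotSet:
    """Nodes whose stationary probability reaches the given quantile of the
    distribution (inclusive); all ties kept, ordered by (-pi, symbol)."""
    cut = float(np.quantile(dist.pi, quantile))
    kept = [
        (node, p) for node, p in zip(dist.node_order, dist.pi) if p >= cut
    ]
    kept.sort(key=lambda t: (-t[1], t[0]))
    return HotspotSet(
        population=population,
        intermediates=[node for node, _ in kept],
        quantile_cut=cut,
    )
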