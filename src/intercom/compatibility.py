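"""Signed-path propagation from hotspot intermediates to interface TFs,
hypergeometric compatibility testing, and functional-receptor selection.

The direction a signaling path predicts for a TF's targets is the product of
the intermediate's binary expression state, the path sign, and each target's
regulon sign; compatibility holds when predicted-active and observed-active
target sets overlap more than chance allows (one-sided hypergeometric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom

from .expression import ExpressionMatrix, PopulationProfile, joint_expression_fraction
from .errors import ValidationError
from .knowledge_base import Regulon, SignalingNetwork
from .markov_signaling import HotspotSet
from .tf_core import PreservedTFSet

logger = logging.getLogger(__name__)

DEFAULT_MAX_PATH_LEN = 5
PATHS_PER_SOURCE_CAP = 10_000


@dataclass(frozen=True)
class SignedPath:
    nodes: tuple[str, ...]
    sign: int  # product of edge signs along the path

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


@dataclass
class CompatibilityResult:
    intermediate: str
    tf: str
    path_sign: int
    N: int  # testable (measured) regulon targets
    K: int  # observed-active targets
    n: int  # predicted-active targets
    k: int  # overlap: predicted-active AND observed-active
    p_value: float
    compatible: bool
    reason: str = ""


@dataclass
class FunctionalReceptorSet:
    population: str
    receptors: list[str]
    supporting: dict[str, list[dict]] = field(default_factory=dict)


def interface_tfs(
    network: SignalingNetwork,
    regulons: dict[str, Regulon],
    preserved: PreservedTFSet,
) -> set[str]:
    """Preserved TFs that bridge signaling and regulation: they own a regulon
    and receive at least one signaling edge."""
    with_incoming = {e.target for e in network.edges}
    result = {
        tf for tf in preserved.tfs if tf in regulons and tf in with_incoming
    }
    if not result:
        raise ValidationError(
            f"population {preserved.population!r}: no preserved TF is reachable "
            "through the signaling network (no interface TFs)"
        )
    return result


def _signed_digraph(network: SignalingNetwork) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(network.nodes)
    for e in network.edges:
        G.add_edge(e.source, e.target, sign=e.sign)
    return G


def signed_paths(
    network: SignalingNetwork | nx.DiGraph,
    source: str,
    targets: set[str],
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
    cap: int = PATHS_PER_SOURCE_CAP,
) -> list[SignedPath]:
    """All simple paths from ``source`` to any target, up to ``max_path_len``
    edges, each annotated with the product of its edge signs.

    Enumeration is capped per source (with a warning) to bound the exponential
    blow-up on dense graphs.
    """
    G = network if isinstance(network, nx.DiGraph) else _signed_digraph(network)
    if source not in G:
        raise KeyError(f"source node {source!r} not in network")
    wanted = {t for t in targets if t in G and t != source}
    out: list[SignedPath] = []
    for path in nx.all_simple_paths(G, source, wanted, cutoff=max_path_len):
        sign = 1
        for u, v in zip(path, path[1:]):
            sign *= G.edges[u, v]["sign"]
        out.append(SignedPath(nodes=tuple(path), sign=sign))
        if len(out) >= cap:
            logger.warning(
                "path enumeration from %r capped at %d paths", source, cap
            )
            break
    return out


def compatibility_test(
    intermediate_state: int,
    path_sign: int,
    regulon: Regulon,
    binary_targets: dict[str, int],
    alpha: float = 0.05,
    intermediate: str = "",
) -> CompatibilityResult:
    """Test agreement between predicted and observed target activity.

    Predicted state of target t = intermediate_state * path_sign * regulon
    sign of t.  Over the N measured targets: K observed active, n predicted
    active, k in both; p = upper-tail hypergeometric P(X >= k | N, K, n).
    """
    measured = [(t, s) for t, s in regulon.targets if t in binary_targets]
    N = len(measured)
    if N == 0:
        return CompatibilityResult(
            intermediate=intermediate, tf=regulon.tf, path_sign=path_sign,
            N=0, K=0, n=0, k=0, p_value=1.0, compatible=False,
            reason="no measured regulon target",
        )
    predicted = {t: intermediate_state * path_sign * s for t, s in measured}
    observed = {t: binary_targets[t] for t, _ in measured}
    K = sum(1 for t in observed if observed[t] == 1)
    n = sum(1 for t in predicted if predicted[t] == 1)
    k = sum(1 for t in predicted if predicted[t] == 1 and observed[t] == 1)
    # P(X >= k) with X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    return CompatibilityResult(
        intermediate=intermediate, tf=regulon.tf, path_sign=path_sign,
        N=N, K=K, n=n, k=k, p_value=p, compatible=bool(p < alpha),
    )


def assess_compatibility(
    network: SignalingNetwork,
    hotspots: HotspotSet,
    iface_tfs: set[str],
    regulons: dict[str, Regulon],
    profile: PopulationProfile,
    alpha: float = 0.05,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> list[CompatibilityResult]:
    """Run the compatibility test for every hotspot intermediate against every
    interface TF it can reach.

    A TF-intermediate pair is compatible if ANY available path sign yields
    p < alpha; when parallel paths disagree in sign, both signs are tested.
    """
    G = _signed_digraph(network)
    results: list[CompatibilityResult] = []
    for interm in hotspots.intermediates:
        if interm not in G:
            continue
        paths = signed_paths(G, interm, iface_tfs, max_path_len=max_path_len)
        by_tf: dict[str, set[int]] = {}
        for p in paths:
            by_tf.setdefault(p.nodes[-1], set()).add(p.sign)
        state = profile.state(interm)
        for tf in sorted(by_tf):
            regulon = regulons[tf]
            binary = {
                t: profile.state(t)
                for t, _ in regulon.targets
                if profile.has_gene(t)
            }
            for sign in sorted(by_tf[tf], reverse=True):
                results.append(
                    compatibility_test(
                        state, sign, regulon, binary, alpha=alpha, intermediate=interm
                    )
                )
    return results


def functional_receptors(
    network: SignalingNetwork,
    hotspots: HotspotSet,
    compat: list[CompatibilityResult],
    submatrix: ExpressionMatrix,
    profile: PopulationProfile,
    regulons: dict[str, Regulon],
    min_cofrac: float = 0.05,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> FunctionalReceptorSet:
    """Receptors with a downstream effect.

    A receptor is functional iff (a) a signaling path of at most
    ``max_path_len`` edges links it to a hotspot intermediate that is
    compatible with some interface TF, and (b) the fraction of the
    population's cells jointly expressing the receptor, that TF, and at least
    one of the TF's observed-active targets is at least ``min_cofrac``.
    """
    compatible = [c for c in compat if c.compatible]
    by_intermediate: dict[str, list[CompatibilityResult]] = {}
    for c in compatible:
        by_intermediate.setdefault(c.intermediate, []).append(c)
    result = FunctionalReceptorSet(population=profile.population, receptors=[])
    if not by_intermediate:
        logger.info("population %r: no compatible intermediate", profile.population)
        return result
    G = _signed_digraph(network)
    hot = set(hotspots.intermediates)
    for receptor in sorted(network.receptors):
        if receptor not in G:
            continue
        reachable = _reachable_within(G, receptor, max_path_len)
        evidence: list[dict] = []
        for interm in sorted(by_intermediate):
            if interm not in hot:
                continue
            if interm != receptor and interm not in reachable:
                continue
            for c in by_intermediate[interm]:
                active_targets = [
                    t
                    for t, _ in regulons[c.tf].targets
                    if profile.state(t) == 1
                ]
                cofrac = joint_expression_fraction(
                    submatrix, [receptor, c.tf], any_of=active_targets
                )
                if cofrac >= min_cofrac:
                    evidence.append(
                        {
                            "intermediate": interm,
                            "tf": c.tf,
                            "path_sign": c.path_sign,
                            "p_value": c.p_value,
                            "co_expression_fraction": cofrac,
                        }
                    )
        if evidence:
            result.receptors.append(receptor)
            result.supporting[receptor] = evidence
    if not result.receptors:
        logger.info("population %r: no functional receptor", profile.population)
    return result


def _reachable_within(G: nx.DiGraph, source: str, max_len: int) -> set[str]:
    """Nodes reachable from source within max_len edges (shortest-path bound;
    a shortest path is simple, so this witnesses a simple path)."""
    lengths = nx.single_source_shortest_path_length(G, source, cutoff=max_len)
    return {node for node, d in lengths.items() if d > 0}
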