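"""Prior-knowledge tables: ligand-receptor scaffold, signaling network, regulons.

All three inputs are tab-delimited text with a mandatory header row; lines
starting with ``#`` are skipped.  Gene identifiers are matched case-sensitively
against the expression matrix gene universe (no alias resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: accepted spellings for edge signs, lower-cased
_SIGN_VOCAB = {
    "1": 1,
    "+1": 1,
    "1.0": 1,
    "activation": 1,
    "-1": -1,
    "-1.0": -1,
    "inhibition": -1,
}

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class LRPair:
    """One ligand-receptor binding pair; autocrine-style self pairs are legal."""

    ligand: str
    receptor: str
    secreted: bool = True


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: int  # +1 activation, -1 inhibition; never 0

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")


@dataclass
class SignalingNetwork:
    """Directed signed graph over signaling molecules.

    Role flags are recomputed by :meth:`KnowledgeBase.refresh_roles` once the
    scaffold and regulons are known; a node may carry several roles.
    """

    nodes: list[str]
    edges: list[SignedEdge]
    receptors: set[str] = field(default_factory=set)
    interface_tfs: set[str] = field(default_factory=set)

    @property
    def intermediates(self) -> set[str]:
        return set(self.nodes) - self.receptors - self.interface_tfs

    def incoming(self, node: str) -> list[SignedEdge]:
        return [e for e in self.edges if e.target == node]

    def validate(self) -> None:
        endpoints = {e.source for e in self.edges} | {e.target for e in self.edges}
        missing = endpoints - set(self.nodes)
        if missing:
            raise ValidationError(f"edge endpoints missing from node list: {sorted(missing)}")


@dataclass
class Regulon:
    """A TF with its directly regulated targets and regulation signs."""

    tf: str
    targets: list[tuple[str, int]]

    def target_genes(self) -> list[str]:
        return [t for t, _ in self.targets]

    def sign_of(self, gene: str) -> int:
        for t, s in self.targets:
            if t == gene:
                return s
        raise KeyError(gene)


@dataclass
class KnowledgeBase:
    scaffold: list[LRPair]
    signaling: SignalingNetwork
    regulons: dict[str, Regulon]

    def refresh_roles(self) -> None:
        """Recompute node role flags from the current scaffold and regulons.

        A node is an interface TF iff it owns a regulon AND has at least one
        incoming signaling edge; receptors are scaffold receptors present in
        the network.
        """
        nodes = set(self.signaling.nodes)
        self.signaling.receptors = {p.receptor for p in self.scaffold} & nodes
        with_incoming = {e.target for e in self.signaling.edges}
        self.signaling.interface_tfs = {
            tf for tf in self.regulons if tf in nodes and tf in with_incoming
        }

    def all_genes(self) -> set[str]:
        genes = set(self.signaling.nodes)
        for p in self.scaffold:
            genes.add(p.ligand)
            genes.add(p.receptor)
        for reg in self.regulons.values():
            genes.add(reg.tf)
            genes.update(reg.target_genes())
        return genes


def _read_table(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_sign(raw, path) -> int:
    key = str(raw).strip().lower()
    if key not in _SIGN_VOCAB:
        raise FormatError(f"{path}: unparseable sign value {raw!r}")
    return _SIGN_VOCAB[key]


def _parse_bool(raw) -> bool:
    key = str(raw).strip().lower()
    if key in _TRUE_STRINGS:
        return True
    if key in _FALSE_STRINGS:
        return False
    raise FormatError(f"unparseable boolean value {raw!r}")


def load_lr_scaffold(path) -> list[LRPair]:
    """Load the ligand-receptor scaffold TSV.

    Requires ``ligand`` and ``receptor`` columns.  If no ``secreted`` column is
    present every ligand is assumed secreted and a warning is logged, so
    pre-curated scaffolds are accepted as-is.  Duplicate (ligand, receptor)
    rows collapse to one pair (first occurrence wins).
    """
    df = _read_table(path, ["ligand", "receptor"])
    if df.empty:
        raise ValidationError(f"{path}: scaffold table is empty")
    has_secreted = "secreted" in df.columns
    if not has_secreted:
        logger.warning("%s: no 'secreted' column; assuming all ligands secreted", path)
    pairs: list[LRPair] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        lig, rec = str(row.ligand).strip(), str(row.receptor).strip()
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        secreted = _parse_bool(row.secreted) if has_secreted else True
        pairs.append(LRPair(lig, rec, secreted))
    return pairs


def filter_secreted(pairs: list[LRPair]) -> list[LRPair]:
    """Keep only pairs with a secreted ligand, preserving order."""
    return [p for p in pairs if p.secreted]


def _collapse_signed_edges(rows, path, what: str):
    """Deduplicate (source, target) entries; opposite-sign conflicts are dropped.

    A conflicting duplicate means the effect is not known, so the edge carries
    no usable evidence.  Returns (edges, n_conflicts_dropped).
    """
    signs: dict[tuple[str, str], set[int]] = {}
    order: list[tuple[str, str]] = []
    for src, tgt, sign in rows:
        key = (src, tgt)
        if key not in signs:
            signs[key] = set()
            order.append(key)
        signs[key].add(sign)
    kept, conflicts = [], 0
    for key in order:
        if len(signs[key]) > 1:
            conflicts += 1
            continue
        kept.append((key[0], key[1], next(iter(signs[key]))))
    if conflicts:
        logger.warning("%s: dropped %d %s edge(s) with conflicting signs", path, conflicts, what)
    return kept, conflicts


def load_signaling_network(path) -> SignalingNetwork:
    """Load the signed directed signaling-network TSV (source, target, sign).

    Self-loops are dropped with a warning; duplicate edges are collapsed and
    sign conflicts discarded as ambiguous evidence.
    """
    df = _read_table(path, ["source", "target", "sign"])
    rows = []
    self_loops = 0
    for row in df.itertuples(index=False):
        src, tgt = str(row.source).strip(), str(row.target).strip()
        sign = _parse_sign(row.sign, path)
        if src == tgt:
            self_loops += 1
            continue
        rows.append((src, tgt, sign))
    if self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    kept, _ = _collapse_signed_edges(rows, path, "signaling")
    edges = [SignedEdge(s, t, g) for s, t, g in kept]
    nodes: list[str] = []
    seen: set[str] = set()
    for e in edges:
        for n in (e.source, e.target):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
    net = SignalingNetwork(nodes=nodes, edges=edges)
    net.validate()
    return net


def load_regulons(path) -> dict[str, Regulon]:
    """Load the gene-regulatory TSV (tf, target, sign) into regulons.

    Rows whose sign is missing, zero, or outside the vocabulary are rejected
    with a counted warning: only regulations with a known effect are usable.
    """
    df = _read_table(path, ["tf", "target", "sign"])
    rows = []
    rejected = 0
    for row in df.itertuples(index=False):
        tf, tgt = str(row.tf).strip(), str(row.target).strip()
        try:
            sign = _parse_sign(row.sign, path)
        except FormatError:
            rejected += 1
            continue
        rows.append((tf, tgt, sign))
    if rejected:
        logger.warning("%s: rejected %d regulon row(s) with unknown effect", path, rejected)
    kept, _ = _collapse_signed_edges(rows, path, "regulon")
    regulons: dict[str, Regulon] = {}
    for tf, tgt, sign in kept:
        regulons.setdefault(tf, Regulon(tf, [])).targets.append((tgt, sign))
    return regulons


def restrict_to_universe(kb: KnowledgeBase, genes: set[str]) -> KnowledgeBase:
    """Drop every scaffold pair, signaling edge, and regulon entry that
    mentions a gene absent from the measured universe, then recompute roles.

    Raises :class:`ValidationError` if the restriction empties the scaffold or
    the signaling network, naming the cause.  Idempotent.
    """
    if not genes:
        raise ValidationError("gene universe is empty")

    scaffold = [p for p in kb.scaffold if p.ligand in genes and p.receptor in genes]
    n_pairs_removed = len(kb.scaffold) - len(scaffold)

    edges = [e for e in kb.signaling.edges if e.source in genes and e.target in genes]
    n_edges_removed = len(kb.signaling.edges) - len(edges)
    nodes = [n for n in kb.signaling.nodes if n in genes]
    # drop nodes that lost every edge AND are not referenced anywhere else
    endpoint = {e.source for e in edges} | {e.target for e in edges}
    nodes = [n for n in nodes if n in endpoint]

    regulons: dict[str, Regulon] = {}
    n_targets_removed = 0
    for tf, reg in kb.regulons.items():
        if tf not in genes:
            n_targets_removed += len(reg.targets)
            continue
        targets = [(t, s) for t, s in reg.targets if t in genes]
        n_targets_removed += len(reg.targets) - len(targets)
        if targets:
            regulons[tf] = Regulon(tf, targets)

    logger.info(
        "universe restriction removed %d scaffold pair(s), %d signaling edge(s), "
        "%d regulon target(s)",
        n_pairs_removed, n_edges_removed, n_targets_removed,
    )
    if not scaffold:
        raise ValidationError(
            "ligand-receptor scaffold is empty after restriction to measured genes"
        )
    if not edges:
        raise ValidationError(
            "signaling network is empty after restriction to measured genes"
        )
    restricted = KnowledgeBase(
        scaffold=scaffold,
        signaling=SignalingNetwork(nodes=nodes, edges=edges),
        regulons=regulons,
    )
    restricted.signaling.validate()
    restricted.refresh_roles()
    return restricted
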