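"""Interaction establishment, scoring, and significance flagging.

An interaction between an ordered (sender, receiver) population pair is
established when the scaffold contains the pair, the ligand is expressed in
more than 5% of sender cells (strict), and the receptor has a downstream
effect in the receiver (functional).  The score is the product of the average
ligand expression over ligand-expressing sender cells and the average receptor
expression over receptor-expressing receiver cells; scores in the top decile
of the null distribution are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compatibility import (
    FunctionalReceptorSet,
    functional_receptors,
    interface_tfs,
    assess_compatibility,
)
from .config import RunConfig
from .errors import ConvergenceError, InterComError, ValidationError
from .expression import (
    ExpressionMatrix,
    PopulationAnnotation,
    PopulationProfile,
    profile_matrix,
    split_populations,
)
from .knowledge_base import KnowledgeBase, LRPair, restrict_to_universe
from .markov_signaling import (
    HotspotSet,
    build_transition_matrix,
    node_weights,
    select_intermediates,
    stationary_distribution,
)
from .tf_core import preserved_tfs

logger = logging.getLogger(__name__)


@dataclass
class Interaction:
    sender: str
    receiver: str
    ligand: str
    receptor: str
    ligand_fraction: float
    receptor_fraction: float
    score: float
    significant: bool


@dataclass
class InteractionTable:
    interactions: list[Interaction]
    metadata: dict = field(default_factory=dict)

    COLUMNS = [
        "sender", "receiver", "ligand", "receptor",
        "ligand_fraction", "receptor_fraction", "score", "significant",
    ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sender": i.sender,
                    "receiver": i.receiver,
                    "ligand": i.ligand,
                    "receptor": i.receptor,
                    "ligand_fraction": i.ligand_fraction,
                    "receptor_fraction": i.receptor_fraction,
                    "score": i.score,
                    "significant": i.significant,
                }
                for i in self.interactions
            ],
            columns=self.COLUMNS,
        )

    def to_heatmap_frame(self) -> pd.DataFrame:
        """Wide matrix: rows 'LIGAND-RECEPTOR', columns 'sender-receiver',
        values = score (0 where an interaction was not established)."""
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame()
        df = df.assign(
            pair=df["ligand"] + "-" + df["receptor"],
            channel=df["sender"] + "-" + df["receiver"],
        )
        wide = df.pivot_table(
            index="pair", columns="channel", values="score", fill_value=0.0
        )
        return wide.sort_index()


@dataclass
class PopulationState:
    """Everything the pipeline derives for one population."""

    profile: PopulationProfile
    submatrix: ExpressionMatrix
    hotspots: HotspotSet
    compat: list
    receptors: FunctionalReceptorSet
    stationary: object = None
    failure: str | None = None  # set when a stage could not be grounded


@dataclass
class PipelineResult:
    table: InteractionTable
    populations: dict[str, PopulationState]
    kb: KnowledgeBase


def candidate_interactions(
    scaffold: list[LRPair],
    sender_profile: PopulationProfile,
    receiver_receptors: set[str],
    min_ligand_frac: float = 0.05,
) -> list[tuple[str, str]]:
    """Scaffold pairs with a functional receiver receptor and a sender ligand
    expressed in strictly more than ``min_ligand_frac`` of cells."""
    out = []
    for p in scaffold:
        if p.receptor not in receiver_receptors:
            continue
        if sender_profile.fraction(p.ligand) <= min_ligand_frac:
            continue
        out.append((p.ligand, p.receptor))
    return out


def interaction_score(
    ligand: str,
    receptor: str,
    sender_profile: PopulationProfile,
    receiver_profile: PopulationProfile,
) -> float:
    """Product of mean ligand expression over expressing sender cells and mean
    receptor expression over expressing receiver cells."""
    return sender_profile.mean(ligand) * receiver_profile.mean(receptor)


def flag_significant(
    candidate_scores: list[float],
    reference_scores: list[float],
    quantile: float = 0.90,
) -> list[bool]:
    """Flag candidate scores at or above the given quantile of the reference
    distribution (linear-interpolation quantile, inclusive)."""
    if not candidate_scores:
        return []
    if not reference_scores:
        raise ValidationError("empty reference score set")
    cut = float(np.quantile(np.asarray(reference_scores, dtype=float), quantile))
    return [s >= cut for s in candidate_scores]


def _analyse_population(
    pop: str,
    submatrix: ExpressionMatrix,
    kb: KnowledgeBase,
    cfg: RunConfig,
) -> PopulationState:
    profile = profile_matrix(submatrix, pop)
    try:
        preserved = preserved_tfs(
            profile, set(kb.regulons), percentile=cfg.tf_percentile, mode=cfg.tf_mode
        )
        iface = interface_tfs(kb.signaling, kb.regulons, preserved)
    except ValidationError as exc:
        logger.warning("population %r: %s", pop, exc)
        empty_hot = HotspotSet(population=pop, intermediates=[], quantile_cut=float("nan"))
        return PopulationState(
            profile=profile, submatrix=submatrix, hotspots=empty_hot,
            compat=[], receptors=FunctionalReceptorSet(pop, []), failure=str(exc),
        )

    weights = node_weights(profile, kb.signaling.nodes, mode=cfg.weight_mode)
    T = build_transition_matrix(kb.signaling, weights, damping=cfg.damping)
    try:
        pi = stationary_distribution(T)
    except ConvergenceError:
        logger.warning(
            "population %r: chain did not converge at damping %.3g; retrying "
            "with damping 0.05", pop, cfg.damping,
        )
        T = build_transition_matrix(kb.signaling, weights, damping=0.05)
        pi = stationary_distribution(T)
    hotspots = select_intermediates(pi, quantile=cfg.hotspot_quantile, population=pop)

    compat = assess_compatibility(
        kb.signaling, hotspots, iface, kb.regulons, profile,
        alpha=cfg.alpha, max_path_len=cfg.max_path_len,
    )
    receptors = functional_receptors(
        kb.signaling, hotspots, compat, submatrix, profile, kb.regulons,
        min_cofrac=cfg.min_cofrac, max_path_len=cfg.max_path_len,
    )
    return PopulationState(
        profile=profile, submatrix=submatrix, hotspots=hotspots,
        compat=compat, receptors=receptors, stationary=pi,
    )


def run_pipeline(
    matrix: ExpressionMatrix,
    annotation: PopulationAnnotation,
    kb: KnowledgeBase,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full inference for every ordered population pair (self-pairs
    included) and return the interaction table plus per-population state."""
    cfg = config or RunConfig()
    kb = restrict_to_universe(kb, set(matrix.gene_ids))
    submatrices = split_populations(matrix, annotation, min_cells=cfg.min_cells)

    states: dict[str, PopulationState] = {}
    for pop, sub in submatrices.items():
        try:
            states[pop] = _analyse_population(pop, sub, kb, cfg)
        except InterComError as exc:
            raise type(exc)(f"population {pop!r}: {exc}") from exc

    interactions: list[Interaction] = []
    pops = sorted(states)
    for sender in pops:
        for receiver in pops:
            s_state, r_state = states[sender], states[receiver]
            receptor_set = set(r_state.receptors.receptors)
            candidates = candidate_interactions(
                kb.scaffold, s_state.profile, receptor_set,
                min_ligand_frac=cfg.min_ligand_frac,
            )
            if not candidates:
                continue
            cand_scores = [
                interaction_score(l, r, s_state.profile, r_state.profile)
                for l, r in candidates
            ]
            if cfg.null_set == "scaffold":
                reference = [
                    interaction_score(p.ligand, p.receptor, s_state.profile, r_state.profile)
                    for p in kb.scaffold
                ]
            else:
                reference = list(cand_scores)
            flags = flag_significant(cand_scores, reference, quantile=cfg.score_quantile)
            for (lig, rec), score, sig in zip(candidates, cand_scores, flags):
                interactions.append(
                    Interaction(
                        sender=sender,
                        receiver=receiver,
                        ligand=lig,
                        receptor=rec,
                        ligand_fraction=s_state.profile.fraction(lig),
                        receptor_fraction=r_state.profile.fraction(rec),
                        score=score,
                        significant=sig,
                    )
                )

    interactions.sort(key=lambda i: (i.sender, i.receiver, -i.score, i.ligand, i.receptor))
    table = InteractionTable(
        interactions=interactions,
        metadata={"config": cfg.to_dict(), "populations": pops},
    )
    return PipelineResult(table=table, populations=states, kb=kb)


def run_intercom(
    matrix: ExpressionMatrix,
    annotation: PopulationAnnotation,
    kb: KnowledgeBase,
    config: RunConfig | None = None,
) -> InteractionTable:
    """Convenience wrapper returning only the interaction table."""
    return run_pipeline(matrix, annotation, kb, config).table
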