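"""Self-contained synthetic fixtures: prior-knowledge tables plus a
multi-population count matrix with a planted signaling chain.

The planted scenario wires a secreted ligand L* (elevated in the sender
population) to a receptor R* whose downstream cascade, interface TF T*, and
positively regulated targets are elevated in the receiver population; T*'s
negatively regulated targets are silenced there.  A bystander population is
pure background.  Everything is deterministic given one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .expression import ExpressionMatrix, PopulationAnnotation
from .knowledge_base import (
    KnowledgeBase,
    LRPair,
    Regulon,
    SignalingNetwork,
    SignedEdge,
)

PLANTED_LIGAND = "LIGSTAR"
PLANTED_RECEPTOR = "RECSTAR"
PLANTED_CASCADE = ("INTSTAR1", "INTSTAR2")
PLANTED_TF = "TFSTAR"
LOW_LIGAND = "LIGLOW"  # simulated below the 5% establishment threshold

SENDER, RECEIVER, BYSTANDER = "sender", "receiver", "bystander"


@dataclass
class KnowledgeTables:
    """Generated prior knowledge as data frames plus the parsed objects."""

    scaffold: pd.DataFrame  # ligand, receptor, secreted
    signaling: pd.DataFrame  # source, target, sign
    regulons: pd.DataFrame  # tf, target, sign
    kb: KnowledgeBase
    planted_pos_targets: list[str]
    planted_neg_targets: list[str]


@dataclass
class PlantedScenario:
    seed: int
    n_cells: int = 200
    n_extra_genes: int = 60
    effect_size: float = 4.0  # fold-elevation of expressed fraction
    background_mean: float = 0.3
    dispersion: float = 2.0
    dropout_keep_range: tuple[float, float] = (0.45, 1.0)
    planted_count_boost: float = 2.5  # extra Poisson mean on expressing planted cells
    n_receptors: int = 20
    n_intermediates: int = 30
    n_tfs: int = 10
    n_targets_per_tf: int = 8
    edge_density: float = 0.08
    populations: tuple[str, ...] = (SENDER, RECEIVER, BYSTANDER)

    def __post_init__(self):
        if self.effect_size <= 1:
            raise ValueError("effect size must exceed 1")
        if self.n_cells < 1:
            raise ValueError("need at least one cell per population")

    @property
    def planted_pair(self) -> tuple[str, str]:
        return (PLANTED_LIGAND, PLANTED_RECEPTOR)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_knowledge(
    seed: int,
    n_receptors: int = 20,
    n_intermediates: int = 30,
    n_tfs: int = 10,
    n_targets_per_tf: int = 8,
    edge_density: float = 0.08,
) -> KnowledgeTables:
    """Random layered signed signaling graph (receptors -> intermediates ->
    TFs, plus cross edges), regulons, and a secreted-ligand scaffold.

    Always contains the all-positive planted chain
    L* -> R* -> INTSTAR1 -> INTSTAR2 -> T* and T*'s regulon with 5 positively
    and 5 negatively regulated dedicated targets.
    """
    if min(n_receptors, n_intermediates, n_tfs, n_targets_per_tf) < 1:
        raise ValueError("all knowledge sizes must be >= 1")
    rng = _rng(seed)

    receptors = [PLANTED_RECEPTOR] + [f"REC{i:03d}" for i in range(1, n_receptors)]
    intermediates = list(PLANTED_CASCADE) + [
        f"INT{i:03d}" for i in range(len(PLANTED_CASCADE), n_intermediates)
    ]
    tfs = [PLANTED_TF] + [f"TF{i:03d}" for i in range(1, n_tfs)]
    ligands = [PLANTED_LIGAND, LOW_LIGAND] + [f"LIG{i:03d}" for i in range(2, n_receptors)]

    def rand_sign() -> int:
        return 1 if rng.random() < 0.7 else -1

    edges: dict[tuple[str, str], int] = {}

    def add_edge(src: str, tgt: str, sign: int | None = None) -> None:
        if src != tgt and (src, tgt) not in edges:
            edges[(src, tgt)] = sign if sign is not None else rand_sign()

    # planted chain, all activating
    add_edge(PLANTED_RECEPTOR, PLANTED_CASCADE[0], 1)
    add_edge(PLANTED_CASCADE[0], PLANTED_CASCADE[1], 1)
    add_edge(PLANTED_CASCADE[1], PLANTED_TF, 1)

    # every receptor feeds at least one intermediate
    for rec in receptors:
        for tgt in rng.choice(intermediates, size=rng.integers(1, 4), replace=False):
            add_edge(rec, str(tgt))
    # intermediate cross-wiring
    for src in intermediates:
        for tgt in intermediates:
            if src != tgt and rng.random() < edge_density:
                add_edge(src, tgt)
    # every TF receives at least one intermediate edge
    for tf in tfs:
        for src in rng.choice(intermediates, size=rng.integers(1, 3), replace=False):
            add_edge(str(src), tf)
    # extra intermediate -> TF edges
    for src in intermediates:
        for tf in tfs:
            if rng.random() < edge_density / 2:
                add_edge(src, tf)

    edge_rows = [(s, t, g) for (s, t), g in sorted(edges.items())]
    signaling_df = pd.DataFrame(edge_rows, columns=["source", "target", "sign"])

    # regulons: planted TF gets dedicated +/- targets, others draw from a pool
    pos_targets = [f"TGTSTARP{i}" for i in range(5)]
    neg_targets = [f"TGTSTARN{i}" for i in range(5)]
    pool = [f"TGT{i:03d}" for i in range(max(n_tfs * n_targets_per_tf // 2, n_targets_per_tf))]
    reg_rows = [(PLANTED_TF, t, 1) for t in pos_targets]
    reg_rows += [(PLANTED_TF, t, -1) for t in neg_targets]
    for tf in tfs[1:]:
        chosen = rng.choice(pool, size=min(n_targets_per_tf, len(pool)), replace=False)
        for tgt in chosen:
            reg_rows.append((tf, str(tgt), rand_sign()))
    regulons_df = pd.DataFrame(reg_rows, columns=["tf", "target", "sign"])

    # scaffold: planted pair, a sub-threshold ligand on the same receptor,
    # and random secreted pairs (a couple non-secreted to exercise the filter)
    scaffold_rows = [
        (PLANTED_LIGAND, PLANTED_RECEPTOR, 1),
        (LOW_LIGAND, PLANTED_RECEPTOR, 1),
    ]
    for lig in ligands[2:]:
        rec = str(rng.choice(receptors))
        secreted = 0 if rng.random() < 0.1 else 1
        scaffold_rows.append((lig, rec, secreted))
    scaffold_df = pd.DataFrame(scaffold_rows, columns=["ligand", "receptor", "secreted"])

    kb = _tables_to_kb(scaffold_df, signaling_df, regulons_df)
    return KnowledgeTables(
        scaffold=scaffold_df,
        signaling=signaling_df,
        regulons=regulons_df,
        kb=kb,
        planted_pos_targets=pos_targets,
        planted_neg_targets=neg_targets,
    )


def _tables_to_kb(scaffold_df, signaling_df, regulons_df) -> KnowledgeBase:
    scaffold = [
        LRPair(str(r.ligand), str(r.receptor), bool(int(r.secreted)))
        for r in scaffold_df.itertuples(index=False)
    ]
    edges = [
        SignedEdge(str(r.source), str(r.target), int(r.sign))
        for r in signaling_df.itertuples(index=False)
    ]
    nodes: list[str] = []
    seen: set[str] = set()
    for e in edges:
        for nd in (e.source, e.target):
            if nd not in seen:
                seen.add(nd)
                nodes.append(nd)
    regulons: dict[str, Regulon] = {}
    for r in regulons_df.itertuples(index=False):
        regulons.setdefault(str(r.tf), Regulon(str(r.tf), [])).targets.append(
            (str(r.target), int(r.sign))
        )
    kb = KnowledgeBase(
        scaffold=scaffold,
        signaling=SignalingNetwork(nodes=nodes, edges=edges),
        regulons=regulons,
    )
    kb.refresh_roles()
    return kb


def _expected_background_fraction(scenario: PlantedScenario) -> float:
    """Analytic expected expressed fraction of a background gene (NB detection
    probability times the mean dropout keep rate)."""
    r, m = scenario.dispersion, scenario.background_mean
    p_detect = 1.0 - (r / (r + m)) ** r
    keep = float(np.mean(scenario.dropout_keep_range))
    return p_detect * keep


def simulate_counts(
    scenario: PlantedScenario,
    knowledge: KnowledgeTables | None = None,
) -> tuple[ExpressionMatrix, PopulationAnnotation]:
    """Simulate the cells x genes count matrix for a planted scenario.

    Background genes are negative binomial with per-gene multiplicative
    dropout (expressed fraction roughly 0.1-0.3).  Planted genes are elevated
    to an expressed fraction of ``effect_size`` times the background
    expectation (capped at 0.9) with boosted counts; T*'s negative targets
    are silenced in the receiver.
    """
    rng = _rng(scenario.seed)
    if knowledge is None:
        knowledge = generate_knowledge(
            scenario.seed,
            n_receptors=scenario.n_receptors,
            n_intermediates=scenario.n_intermediates,
            n_tfs=scenario.n_tfs,
            n_targets_per_tf=scenario.n_targets_per_tf,
            edge_density=scenario.edge_density,
        )
    kb_genes = sorted(knowledge.kb.all_genes())
    genes = kb_genes + [f"BG{i:04d}" for i in range(scenario.n_extra_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}

    elevated: dict[str, list[str]] = {
        SENDER: [PLANTED_LIGAND],
        RECEIVER: [PLANTED_RECEPTOR, *PLANTED_CASCADE, PLANTED_TF,
                   *knowledge.planted_pos_targets],
        BYSTANDER: [],
    }
    silenced: dict[str, list[str]] = {
        SENDER: [],
        RECEIVER: list(knowledge.planted_neg_targets),
        BYSTANDER: [],
    }

    base_frac = _expected_background_fraction(scenario)
    planted_frac = min(0.9, scenario.effect_size * base_frac)

    n_pop = scenario.n_cells
    n_total = n_pop * len(scenario.populations)
    counts = np.zeros((n_total, len(genes)), dtype=np.int64)

    # per-gene dropout keep probability, shared across populations
    lo, hi = scenario.dropout_keep_range
    keep_prob = rng.uniform(lo, hi, size=len(genes))

    r = scenario.dispersion
    nb_p = r / (r + scenario.background_mean)

    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    for p_idx, pop in enumerate(scenario.populations):
        rows = slice(p_idx * n_pop, (p_idx + 1) * n_pop)
        block = rng.negative_binomial(r, nb_p, size=(n_pop, len(genes)))
        block = block * (rng.random((n_pop, len(genes))) < keep_prob)
        for gene in elevated.get(pop, []):
            j = gene_index[gene]
            on = rng.random(n_pop) < planted_frac
            block[:, j] = np.where(
                on, 1 + rng.poisson(scenario.planted_count_boost, size=n_pop), 0
            )
        # the sub-threshold ligand is pinned to exactly 3% of cells everywhere
        j_low = gene_index[LOW_LIGAND]
        block[:, j_low] = 0
        n_low = max(1, int(round(0.03 * n_pop)))
        block[rng.choice(n_pop, size=n_low, replace=False), j_low] = 1
        for gene in silenced.get(pop, []):
            block[:, gene_index[gene]] = 0
        counts[rows] = block
        for i in range(n_pop):
            cid = f"{pop}_{i:04d}"
            cell_ids.append(cid)
            labels[cid] = pop

    matrix = ExpressionMatrix(sp.csr_matrix(counts), cell_ids, genes)
    return matrix, PopulationAnnotation(labels=labels)


def permute_annotation(
    annotation: PopulationAnnotation, seed: int
) -> PopulationAnnotation:
    """Random permutation of the population labels across cells (null model)."""
    rng = _rng(seed)
    cells = list(annotation.labels)
    labels = [annotation.labels[c] for c in cells]
    perm = rng.permutation(len(labels))
    return PopulationAnnotation(
        labels={c: labels[perm[i]] for i, c in enumerate(cells)}
    )


def write_fixture(out_dir, scenario: PlantedScenario) -> dict[str, Path]:
    """Write a complete fixture set consumable by the ``run`` CLI command:
    MTX triplet, annotation TSV, three knowledge TSVs, scenario manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    knowledge = generate_knowledge(
        scenario.seed,
        n_receptors=scenario.n_receptors,
        n_intermediates=scenario.n_intermediates,
        n_tfs=scenario.n_tfs,
        n_targets_per_tf=scenario.n_targets_per_tf,
        edge_density=scenario.edge_density,
    )
    matrix, annotation = simulate_counts(scenario, knowledge)

    paths = {
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "annotation": out / "annotation.tsv",
        "lr": out / "lr_scaffold.tsv",
        "signaling": out / "signaling.tsv",
        "grn": out / "regulons.tsv",
        "manifest": out / "scenario.yaml",
    }
    # genes x cells on disk, matching common single-cell exports
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(matrix.counts.T))
    pd.Series(matrix.cell_ids).to_csv(paths["barcodes"], index=False, header=False)
    pd.Series(matrix.gene_ids).to_csv(paths["features"], index=False, header=False, sep="\t")
    pd.DataFrame(
        {"cell": list(annotation.labels), "population": list(annotation.labels.values())}
    ).to_csv(paths["annotation"], sep="\t", index=False)
    knowledge.scaffold.to_csv(paths["lr"], sep="\t", index=False)
    knowledge.signaling.to_csv(paths["signaling"], sep="\t", index=False)
    knowledge.regulons.to_csv(paths["grn"], sep="\t", index=False)
    manifest = {
        "seed": scenario.seed,
        "n_cells_per_population": scenario.n_cells,
        "populations": list(scenario.populations),
        "planted_pair": list(scenario.planted_pair),
        "cascade": list(PLANTED_CASCADE),
        "interface_tf": PLANTED_TF,
        "positive_targets": knowledge.planted_pos_targets,
        "negative_targets": knowledge.planted_neg_targets,
        "effect_size": scenario.effect_size,
        "background_mean": scenario.background_mean,
        "dispersion": scenario.dispersion,
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return paths
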