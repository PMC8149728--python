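# intercom

Inference of functional, secreted-ligand-mediated cell–cell interactions from
single-cell RNA-seq count data.

The pipeline integrates three layers of evidence for every ordered pair of
annotated cell populations:

1. **Extracellular binding** — a curated ligand–receptor scaffold restricted
   to secreted ligands.
2. **Intracellular signaling** — an expression-weighted finite Markov chain
   over a signed, directed signaling network; nodes with the highest
   stationary probability are signaling hotspots.
3. **Transcriptional regulation** — hotspot intermediates are connected to
   preserved interface transcription factors through signed paths, and the
   direction each path predicts for the TF's regulon targets is tested
   against observed binarized expression with a one-sided hypergeometric test
   (p < 0.05).

A receptor is *functional* when a path links it to a compatible hotspot and
it is co-expressed with the interface TF and its active targets in ≥ 5 % of
cells. An interaction is established when the scaffold contains the pair, the
ligand is expressed in > 5 % of sender cells, and the receptor is functional
in the receiver. Its score is the product of the mean ligand expression (over
ligand-expressing sender cells) and the mean receptor expression (over
receptor-expressing receiver cells); scores in the top decile of all
scaffold-pair scores between the two populations are flagged significant.

## CLI

Generate a fully synthetic fixture (knowledge tables + count matrix with a
planted ligand→receptor→cascade→TF→target signal):

```bash
intercom simulate --seed 1 --out fixture/
```

Run the pipeline:

```bash
intercom run \
  --counts fixture/matrix.mtx \
  --cells fixture/barcodes.tsv --genes fixture/features.tsv \
  --annotation fixture/annotation.tsv \
  --lr fixture/lr_scaffold.tsv \
  --signaling fixture/signaling.tsv \
  --grn fixture/regulons.tsv \
  --out results/
```

Outputs: `interactions.tsv` (long table: sender, receiver, ligand, receptor,
fractions, score, significant), `compatibility.tsv`, `hotspots.tsv`,
`heatmap.tsv` (wide ligand–receptor × sender–receiver score matrix), and
`run_manifest.yaml` (effective configuration + input checksums).

Counts may be a MatrixMarket triplet (genes × cells on disk, as in common
single-cell exports) or a dense CSV/TSV with cells as rows. All knowledge
tables are tab-delimited with a header; signs accept `1`/`-1`/`activation`/
`inhibition`.

Tunables (flag > `--config` YAML > default): `--tf-percentile`, `--tf-mode`,
`--hotspot-quantile`, `--damping`, `--weight-mode`, `--alpha`,
`--max-path-len`, `--min-cofrac`, `--min-ligand-frac`, `--score-quantile`,
`--null-set`, `--min-cells`.

## Library

```python
from intercom import run_intercom, RunConfig
from intercom.synthetic_data import PlantedScenario, generate_knowledge, simulate_counts

knowledge = generate_knowledge(seed=1)
matrix, annotation = simulate_counts(PlantedScenario(seed=1), knowledge)
table = run_intercom(matrix, annotation, knowledge.kb, RunConfig())
print(table.to_frame().head())
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: equivalence of the
stationary distribution with matrix-power and eigenvector oracles,
hypergeometric p-values against exhaustive enumeration, signed-path
enumeration against an independent DFS, planted-interaction recovery and
null calibration over 20 seeds, threshold edge cases, and byte-level
determinism of the output.

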