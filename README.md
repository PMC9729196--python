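# nbpoly

Sequence-based modelling of nanobody polyreactivity.

Nanobodies (VHH single-domain antibodies) raised from synthetic yeast-display
libraries are attractive therapeutics and research reagents, but individual
clones often bind many unrelated biomolecules — *polyreactivity* — which
compromises developability and in vivo behaviour. When a display library is
sorted into low- and high-polyreactivity pools (e.g. by staining with a
solubilized membrane-protein polyspecificity reagent) and both pools are deep
sequenced, the resulting labelled CDR sequences carry enough signal to train
models that score polyreactivity from sequence alone and to design *rescue
mutations* that reduce it.

`nbpoly` is for protein engineers and computational immunologists who have
(or simulate) such sorted pools. It implements the full path from reads to
designs:

- **seqio** — FASTA/FASTQ/TSV input, fixed-frame translation, nanobody
  recovery by the conserved FR4 anchor (`WGQGTQVTVSS`), CDR extraction with a
  framework template, library length filters (CDR1 = 8, CDR2 ∈ {8, 9},
  6 ≤ CDR3 ≤ 22), CDR-level deduplication into labelled pools.
- **numbering** — deterministic IMGT-style slot assignment for fixed-framework
  libraries (CDR1 27–38, CDR2 56–65 with optional extension slot, CDR3
  105–117 plus 111.x/112.x insertions; middle-out gap placement) and the dual
  mutation nomenclature `G26D^27` (sequence position + IMGT slot).
- **features** — aligned one-hot and 1–3-mer count embeddings; baseline
  descriptors: isoelectric point (Henderson–Hasselbalch bisection), mean
  hydrophobicity (Kyte–Doolittle by default), CDR3 length, CDR arginine count.
- **models** — four classifiers under one contract (high score = low
  predicted polyreactivity, reported as log-odds of the low class): one-hot
  logistic regression, k-mer logistic regression, a three-block 1D CNN on the
  aligned grid, and a two-layer GRU (hidden size 128) on the unaligned padded
  sequence. The neural networks are implemented in numpy with manual
  backpropagation and are gradient-checked in the test suite.
- **evaluation** — k-means cluster train/test splits with Levenshtein
  (> 10 edits) and identity (≤ 75 %) constraints between train and test;
  rank-based ROC AUC and Spearman ρ against measured polyreactivity.
- **design** — exhaustive single/double mutational scanning (substitutions,
  insertions, deletions within library bounds), per-model ranking, and
  rescue-panel selection: top-3 singles per CDR (diverse in position and
  residue class), top double within each CDR, top cross-CDR double with a
  novel constituent single; cysteines excluded; near-ties on the one-hot
  score broken by the k-mer score.
- **synthetic** — a generator of sorted pools and index sets with planted
  per-position and motif effects, so every stage is testable end to end.

The statistical core follows the fit/results pattern: build a
`PolyreactivityModel` from two labelled pools and call `.fit()` to obtain a
`PolyreactivityResults` object that scores sequences, exposes weight maps and
serializes to disk.

## Worked example

```python
from nbpoly import (SyntheticConfig, generate_pools, generate_index_set,
                    ModelSpec, train_model, spearman_rho)

pools = generate_pools(SyntheticConfig(n_per_class=2000, seed=1))
model = train_model(ModelSpec("onehot_lr"), pools.low, pools.high)
print(model.summary())

weights = model.position_weight_map()
print("weight of arginine at CDR3 slot 106:", round(weights.loc["106", "R"], 2))
print("weight of aspartate at CDR3 slot 106:", round(weights.loc["106", "D"], 2))

records, measured = generate_index_set(pools.config, n=48)
rho = spearman_rho(model.score(records), [measured[r.id] for r in records])
print("index-set Spearman rho:", round(rho, 2))
```

prints

```
Polyreactivity classifier
========================================
kind:            onehot_lr
train n (low):   2000
train n (high):  2000
frame hash:      2b472f64b52d
seed:            0
L2 strength:     1.0
n parameters:    881
score: log-odds(low class); high score = low predicted polyreactivity

weight of arginine at CDR3 slot 106: -3.08
weight of aspartate at CDR3 slot 106: 3.47
index-set Spearman rho: 0.95
```

The negative arginine weight and positive aspartate weight at the same CDR3
position are the classic polyreactivity signature (basic/aromatic residues
raise nonspecific binding; acidic residues suppress it), recovered here from
the labelled pools. The Spearman ρ measures how well the trained score ranks
an independent panel of 48 clones spanning the polyreactivity range.

A command-line interface mirrors the library:

```bash
nbpoly simulate --seed 1 --out sim/              # synthetic pools + index set
nbpoly train    --pools sim/pools.tsv --out models/
nbpoly evaluate --pools sim/pools.tsv --out eval.tsv
nbpoly score    --in queries.fasta --model-dir models/ --out report.tsv
nbpoly rescue   --in clone.fasta  --model-dir models/ --scan double --out clone
```

`nbpoly score` reports, per query, the IMGT-aligned CDR display, CDR lengths,
isoelectric point, hydrophobicity, per-model scores and the percentile of
each score against the training-pool reference distribution. `nbpoly rescue`
writes the full variant ranking plus the selected rescue panel in dual
nomenclature (e.g. `R98D^115`).

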