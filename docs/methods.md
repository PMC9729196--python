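# Methods

## Problem setting

A synthetic nanobody display library varies three CDR loops on a constant
framework. Sorting the displayed library into low- and high-polyreactivity
pools and deep-sequencing both yields two labelled sets of CDR triples. We
treat polyreactivity prediction as binary classification (class 1 = low
polyreactivity) and expose every model's score as the log-odds of the low
class, so one orientation — *high score = low predicted polyreactivity* —
holds across models, rankings and rescue design.

## Sequence processing

Reads are assumed merged and quality-trimmed upstream. Translation uses the
standard genetic code in a fixed, configurable frame (amplicon primers fix
the frame; no six-frame search); translation stops at the first stop codon
and ambiguous codons yield `X`. The nanobody region is the prefix ending at
the first occurrence of the conserved FR4 beta-strand motif
(`WGQGTQVTVSS` by default, configurable). CDRs are located by exact matching
of the framework template regions; the default template is a representative
synthetic VHH scaffold. Library filters: CDR1 length 8; CDR2 length 8 or 9
(9 or 10 when the extra variable position at the end of CDR2 is modelled);
CDR3 length 6–22; standard residues only (`X`-containing records are
excluded at filter time). Within each pool, records are deduplicated by CDR
triple with read counts summed; both the full-sequence and CDR-triple unique
tallies are retained. CDR triples observed in *both* pools carry
contradictory labels and are removed from both before training — keeping
them would inject label noise with identical features on both sides.

## Numbering

CDRs are laid onto a fixed IMGT-style slot grid: CDR1 on 27–38, CDR2 on
56–65 (the window start is configurable down to 55, since some analyses
include that boundary position), CDR3 on 105–117 with insertion slots. Gap
placement is middle-out: a CDR of length L fills the first ⌈L/2⌉ and last
⌊L/2⌋ slots, leaving central gaps. CDR3 loops longer than 13 fill all
canonical slots and place the excess on insertion labels in the fixed order
112.1, 111.1, 112.2, 111.2, …, displayed in the IMGT convention (ascending
111.x, then descending 112.x). These conventions are deterministic and
documented so trained models are portable; full profile-HMM antibody
numbering is out of scope — queries with foreign frameworks must either
match the configurable framework template or supply CDR boundaries.

Mutations are written in a dual nomenclature: wild-type residue, 1-based
position in the full sequence, new residue, and IMGT slot as superscript
(`G26D^27`). Deletions are written `G26del^27` and insertions `ins26R^111.1`
(the residue is inserted before the stated sequence position); these two
forms are this package's own convention.

## Features

The aligned one-hot embedding has one 20-dimensional block per slot, in
fixed alphabet order; gaps encode as all-zero rather than as a 21st channel,
so logistic weights remain per-amino-acid interpretable and loop length
enters through absent contributions. The k-mer embedding counts motifs of
length 1–3 within each CDR (20 + 400 + 8000 = 8,420 features); windows never
span CDR boundaries because the loops are not adjacent in the folded domain.

Baseline descriptors: isoelectric point is the root of the
Henderson–Hasselbalch net charge (N/C termini plus D, E, C, Y, K, R, H side
chains) found by bisection on [0, 14] to 1e-4, with EMBOSS pKa values by
default (Bjellqvist and Sillero tables selectable); hydrophobicity is the
mean Kyte–Doolittle value (Eisenberg selectable); CDR3 length and CDR
arginine count complete the set. Descriptors are computed on concatenated
CDRs by default (the framework is constant in the library); a flag switches
to the full sequence.

## Models

* **One-hot logistic regression** — L2-penalized (strength 1.0 by default;
  the penalty stabilizes rarely occupied slots), trained to convergence with
  lbfgs. Weights reshape to a (slot × residue) map; negative entries mark
  residue/position combinations predictive of high polyreactivity.
* **k-mer logistic regression** — same training on the 8,420-dimensional
  count vector; the ranked motif table reports both extremes.
* **CNN** — on the aligned one-hot grid as 20 input channels: three blocks
  (conv 20→32 k3 + batch norm + ReLU; conv 32→64 k3 + BN + ReLU + max-pool
  k3 stride 3; conv 64→128 k3 + BN + ReLU + max-pool k3 stride 1) followed
  by a dense layer to one logit.
* **RNN** — a two-layer GRU, hidden size 128, over the unaligned
  concatenated CDRs one-hot-encoded and end-padded to the maximum library
  length; the final hidden state feeds a dense layer. The gated recurrent
  cell is the package's default recurrent unit; it runs forward-only.

The neural networks are implemented directly in numpy with manual
backpropagation (validated against central-difference gradients at 1e-6
relative tolerance) and trained with Adam (lr 1e-3, batch 256, up to 20
epochs, early stopping on a 10 % validation split with patience 3, best
validation parameters restored). Training is bit-for-bit reproducible for a
fixed seed. Read counts are not used as sample weights — training is on
unique sequences — and classes are unweighted by default since sorted pools
are near-balanced. Model archives store the spec, frame-configuration hash
and parameters in a versioned container; loading a mismatched version fails
explicitly.

## Evaluation

Random splits overestimate accuracy because deep-sequenced pools contain
families of near-duplicate clones. Records are therefore k-means-clustered
(Euclidean, on the aligned one-hot embedding; the feature space is a design
choice recorded with the split seed) and whole clusters are held out — the
cluster whose size is closest to the balanced share n/k, so the test set is
neither a singleton nor a majority. Any training record within 10
Levenshtein edits of, or above 75 % identity to, any test record is removed
from the training side (test integrity is preserved by never removing test
records). Identity is defined as aligned matches over the longer
concatenated-CDR length, 1 − d/max(|a|,|b|). Edit distances use edlib with
an early-abort bound during filtering; achieved post-filter minima/maxima
are re-verified exhaustively in tests. AUC is the rank-based Mann–Whitney
statistic with average-rank ties; Spearman ρ is the Pearson correlation of
average ranks (undefined, and rejected, for constant vectors). Descriptor
baselines enter the AUC comparison oriented as scores (acidic pI, lower
hydrophobicity, shorter CDR3, fewer arginines ⇒ low polyreactivity).

## Mutational scanning and rescue panels

Single edits comprise all 19 substitutions per CDR position plus deletions
and insertions wherever the loop stays within library bounds; results are
deduplicated by the resulting CDR triple (inserting a residue next to an
identical one gives one variant, not two). Double edits are all unordered
pairs of single edits at distinct (CDR, position) sites whose combined
result passes the length filters; application in parent coordinates
descending by position makes the combination unambiguous. The stream is
capped (5 × 10⁶ by default) with an explicit overflow error. Rankings are
per model, descending score, ties broken lexicographically by edit label;
the parent is always present as the zero-edit reference.

Panel selection mirrors experimental practice: per CDR the three top singles
— diversified so no two share both position and residue class
(charged/aromatic/polar/aliphatic) — the best double within each CDR, and
for each CDR pair the best spanning double contributing at least one single
not already selected. Cysteine-introducing edits are excluded outright
(risk to the conserved disulfide). When candidates' one-hot scores fall
within ε (default 0.1 log-odds; the threshold for "scored similarly" is not
externally prescribed) the candidate with the higher k-mer score is taken,
to respect local sequence context, and tagged.

## Synthetic study conditions

The generator emulates sorted pools: CDR1 fixed at 8 with one dominant
residue per position (probability 0.7, remainder uniform — "moderate
diversity"), CDR2 of length 8/9 likewise, CDR3 of length 6–22 (triangular
length distribution peaking mid-range) drawn from a mildly skewed
composition typical of synthetic libraries (Y/S/G-rich, some arginine).
Each clone's latent low-polyreactivity propensity is linear in exactly the
features the LR models see: planted per-(slot, residue) weights of ±2 at
positions occupied for every legal loop length (CDR1 tail, CDR2 anchors,
the first/last three CDR3 slots; basic and aromatic residues negative,
acidic positive), compositional 1-mer terms (R −1.0, K −0.8, W −0.8,
D +1.0, E +0.8), a few 2-mer motifs (RR −2, WW −1.5, DE +1.5), plus
Gaussian noise (σ = 0.5 by default). The density of planted effects is
chosen so a typical clone carries several contributions and the latent
spans a wide range — making recovery tests sharp for every model family; an
optional pairwise-interaction term adds signal linear models cannot capture.
Labels come from thresholding at the median (balanced pools) or Bernoulli
draws on the logistic transform. The index-set generator stratifies a large
candidate sample into latent rank-quartiles and samples equally from each,
reporting the latent plus Gaussian measurement noise (σ = 0.25) as the
"measured" value on the score scale.

What the simulation does *not* model: sequencing error, PCR amplification
bias, sort impurity beyond the single noise parameter, framework variation,
and real biophysical couplings between positions. Passing tests therefore
demonstrate that the machinery recovers structure it is designed to recover,
not that the models attain any particular accuracy on laboratory data.

## Problem sizes and numerics

Test and acceptance runs size simulations to single-CPU budgets: logistic
recovery at 20,000 clones per class (σ = 0.5), GRU recovery at 4,000 per
class, CNN recovery at 10,000 per class (where its generalization gap
closes), null calibration for all four models at 2,000 per class with
shortened neural-net schedules (the convex LRs are insensitive to epochs),
split integrity at 500 records with an exhaustive pair scan, and rescue
design with trained LR models at 5,000 per class on a parent with a compact
CDR3 to bound the double-scan size. Bisection tolerance for pI is 1e-4 pH
units; LR convergence tolerance 1e-8; model round-trips are exact for LR and
within 1e-6 for the networks (float32 parameters).

## Known limitations

Framework-exact CDR extraction does not tolerate framework mutations
(humanized or foreign scaffolds need explicit CDR boundaries or a matching
template). The CNN/GRU implementations favour clarity and determinism over
speed and run on one CPU core. The rescue tie-break ε and the diversity
heuristic are documented conventions, not fitted quantities. Cluster-based
splitting assumes the one-hot embedding separates sequence families; wildly
different feature spaces would give different clusters.
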