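# Methods

## Problem and model

Splice-site prediction from DNA alone is a needle-in-a-haystack problem:
the canonical donor/acceptor dinucleotides (GT, AG) appear roughly every
16 bp in random sequence, while true junctions are kilobases apart, and a
small minority of true junctions does not even carry the canonical dimers
(GC-AG and AT-AC introns). splicescan treats the problem as 3-class
classification of fixed-length windows — *acceptor*, *donor*,
*non-splice-site* — so that a single model both discriminates the two
site types and rejects background, and so that non-canonical junctions
are never pre-filtered away by a GT/AG candidate step.

A window of even length L covers genome positions `b − L/2 + 1 .. b + L/2`
for boundary `b`, the 1-based position of the last base before the
junction; the junction therefore sits exactly between window positions
L/2 and L/2+1 (between 200 and 201 at the default L=400). The network is

1. 1-D convolution: 50 kernels of size 9, stride 1, zero padding chosen so
   the feature map keeps length L, ReLU;
2. flatten; fully connected, 100 units, ReLU;
3. dropout, rate 0.30 (training mode only);
4. fully connected, `n_classes` units; softmax.

Inputs are one-hot encoded (A,C,G,T as unit vectors; N as the zero
vector, so unknown bases contribute nothing). Training minimizes softmax
cross-entropy with Adam (learning rate 1e-4, β₁=0.9, β₂=0.999, ε=1e-7),
40 epochs, batch size 50. Defaults follow the printed recipe; every one
of them is a `ModelSpec`/`TrainConfig` field. The default 3-class model
at L=400 has 2,002,253 trainable parameters (conv 1,850; FC1 2,000,100;
FC2 303), which the test suite checks against a closed-form counter.

The network is implemented directly on NumPy (im2col convolution,
explicit backward passes, inverted dropout, Glorot-uniform
initialization). One integer seed drives initialization, minibatch
shuffling and dropout, making every fit bit-reproducible on a given
platform; there is no GPU path, so the usual deep-learning-framework
nondeterminism does not arise.

Design choices where the recipe is silent: ReLU is applied after the
convolution as well as FC1 (conventional; `conv_activation="linear"`
disables it); there is no early stopping or learning-rate schedule — the
validation split is used only for monitoring and for choosing structural
knobs; class label order is fixed as (acceptor, donor, non_splice) and
recorded in saved models.

## Dataset construction

Positives are windows centered on annotated exon boundaries: per
transcript with k ≥ 2 exons sorted by start, the upstream exon end is a
donor boundary and the downstream exon start − 1 an acceptor boundary.
Transcript-terminal boundaries (first exon start, last exon end) are
transcription start/termination sites, not splice junctions, and are
excluded. Sites shared by transcripts are de-duplicated on
(sequence, type, boundary). Initial negatives are centered at
`floor((b_i + b_{i+1})/2)` for adjacent annotated boundaries, excluding
midpoints that coincide with a boundary; midpoints (or sites) whose
window would overrun the sequence are skipped rather than padded — the
model never sees padded context. Windows containing N are kept (zero
rows); an optional `max_n_fraction` filter exists but defaults to off.
Only the forward strand is modeled; minus-strand transcripts are skipped
with a warning, and an opt-in flag maps them to forward coordinates with
the canonical check on the reverse complement.

Rebalancing enforces a 10:1 canonical:non-canonical ratio **within each
positive class**: all available non-canonical windows are kept (up to an
optional cap) and canonical windows are subsampled to exactly ten times
that count. Subsampling canonical (rather than duplicating rare
non-canonical rows) is the default because it introduces no repeated
training rows; oversampling with replacement is available behind a flag.
When canonical windows are too few to support the ratio, the kept
non-canonical count is lowered to `floor(n_canonical/ratio)` so the exact
ratio always holds — the property the tests assert.

Splits are stratified by label: 10% of each class to the test split, then
20% of the remaining training windows to validation, rounded per stratum;
the three splits partition the dataset exactly.

## Hard-negative mining

A model trained on midpoint negatives is nearly perfect on its own test
split yet calls GT/AG lookalikes all over a real scan. The
reconstruction loop therefore alternates training and harvesting: train
from freshly initialized weights on a stratified 90% of the current
dataset (fresh initialization avoids dragging optimizer state across a
changing dataset; warm start is a flag), measure accuracy on the held-out
10%, scan one randomly chosen annotated gene, and add every
false-positive call — argmax donor/acceptor at a position that is not an
annotated boundary of that type — to the negative set as a new
`non_splice` window tagged with the class it was predicted as. Mined
windows are de-duplicated against the existing negative set. Positives
never change; negatives grow monotonically.

"The false-positive count stopped decreasing" is operationalized as a
patience rule on a gene region set aside in advance: stop when the
evaluation FP count has failed to improve on its running best (by more
than `min_relative_decrease`, default 0) for `patience` (default 3)
consecutive iterations, or at `max_iterations` (default 100). The
evaluation region never overlaps mining regions, and any starting-dataset
windows inside it are dropped before the first iteration, so the
stopping signal is measured on sequence the model has never trained on.
Per-iteration seeds derive only from (loop seed, iteration index), which
is what makes `mine --resume` deterministic.

## Scanning and filtering

Scanning classifies every step-strided candidate boundary whose window
fits; a position becomes a call when the argmax class is donor or
acceptor and its probability clears `min_score` (default 0 = argmax).
Because the model is trained only to answer positively when the junction
is centered, step-1 scanning localizes sites to the base. The scan is
contractually identical to classifying each extracted window
independently — a brute-force oracle test enforces exact equality. Calls
are one-per-position; trained models often also fire on neighboring
offsets, so an optional non-maximum-suppression (default off) keeps the
best call within ±k nt. Optional 2-class filters (same architecture,
2-unit output; one per site type, trained on that type's positives
versus the false positives mined while that type was predicted) re-score
calls; filtering never adds calls or moves boundaries.

## Evaluation

Window-level: accuracy plus one-vs-rest AUC, recall = TP/(TP+FN),
precision = TP/(TP+FP) and harmonic-mean F1 for donor and acceptor
separately, at argmax decisions; a class absent from the truth yields
"not applicable", never 0. Scan-level: the false-positive count at a
recall target — sweep the observed score thresholds from high to low and
report FPs at the most stringent threshold whose recall of annotated
sites reaches the target; unattainable targets are flagged rather than
clamped. Matching is position-exact by default (tolerance configurable);
combined two-type counts sum the per-type counts at each type's own
threshold.

## Attribution

Per-nucleotide contributions are gradient × input against an all-zero
reference, taken on the pre-softmax logit of the target class (avoiding
softmax saturation). For ReLU networks with a zero baseline this equals
rescale-rule backpropagated contributions in the non-saturating case and
is exact for linear models (scores sum to logit(x) − logit(0), a unit
test). Profiles average per-position scores over windows within
junction ± flank (default 10, i.e. 20 positions; 191–210 at L=400).
Sequence logos report per-column base frequencies (N excluded) and
information content 2 + Σp·log₂p bits.

## The simulator

The simulator emulates the data regime the method was designed for, on a
single forward-strand chromosome: genes laid left to right with
intergenic gaps; exon/intron/intergenic lengths log-normal with hard
minima; background base composition configurable (uniform by default).
Junctions carry motifs sampled from position probability matrices — a
9-column donor motif (exon −3..−1, intron +1..+6; MAG|GTRAGT-like
consensus, GT fixed) and a 15-column acceptor motif (intron −14..−1,
exon +1; pyrimidine tract then NYAG|G, AG fixed). The PWM values are
hand-set and fixed in code; nothing in the pipeline depends on their
exact numbers, only on the dimers being deterministic. With probability
`non_canonical_fraction` an intron is rewritten as GC-AG or AT-AC
(chosen uniformly, both ends consistently) — note GC-AG leaves the
acceptor canonical, so the site-level non-canonical fraction is about
0.75× the intron-level one and the donor-level fraction tracks it
exactly. `decoy_rate` plants additional PWM-sampled pseudo-motifs per kb
in introns and intergenic sequence (never overlapping exons or true
junction motifs), which is what gives the mining loop genuine false
positives to harvest. An `alt_splicing` flag adds a second,
exon-skipping transcript per gene to exercise site de-duplication
without changing the ground truth.

The emitted FASTA + GTF + ground-truth triple is self-consistent by
construction: deriving sites from the annotation reproduces the ground
truth exactly, for any seed — the suite checks 50.

What the simulator does **not** model: realistic (heavy-tailed human)
intron lengths, branch points, GC-content heterogeneity, repeats,
overlapping or nested genes, expression. Passing the end-to-end tests
therefore shows the pipeline's machinery is correct and that the method
behaves qualitatively as designed (learnable motifs are learned, mined
negatives suppress decoys, non-canonical sites survive rebalancing); it
does not certify real-genome accuracy numbers.

## Study conditions for the end-to-end checks

The reference protocol (`splicescan.protocols`) runs at desk scale on one
CPU: a ~190 kb genome of 40 genes × 26 exons (1000 junctions per type) so
that 1000 windows per class are available at L=100; decoys at 1/kb;
5% non-canonical introns — high enough that a 40-gene genome reliably
contains non-canonical junctions for the rebalance and recovery checks,
while still rare; 20 epochs per fit; 3 mining iterations against a
set-aside gene chosen as the first (by coordinate) containing a
non-canonical junction. The construction-count checks run a larger
genome (1000 genes × 11 exons → 10,000 junctions per type, L=400) through
dataset building and the 10:1 rebalance. These sizes keep the whole suite
within a few minutes while leaving the qualitative behavior — high test
accuracy and AUC, a falling evaluation-region FP trajectory, strictly
growing negatives, recovered non-canonical sites — clearly measurable.

## Numerical notes and limitations

* Probabilities are float32; scan/oracle equality is exact only under
  identical batch partitioning (matrix products are not associative in
  floating point).
* Argmax ties (measure-zero in practice) resolve to the lowest class
  index.
* `fp_at_recall` sweeps only observed scores; an empty call list is
  "unattainable" for any positive target.
* Saved models are a JSON sidecar (spec, label order, history) plus an
  `.npz` weight archive; loading verifies a format version and,
  optionally, the expected class count.
* Training at L=400 with tens of thousands of windows is minutes-scale
  on a single CPU; the heavy FC1 layer (2M weights) dominates.
* Known limitation: position-exact calling tends to fire on ±1–2 nt
  neighbors of strong sites early in training; mining largely removes
  this, and NMS exists for the remainder.
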