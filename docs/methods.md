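# Methods

## The prediction task

Every sample is a genomic position (a candidate breakpoint) represented by
a context window of length *L* over {A,C,G,T}. Insertion and background
windows take the *L*/2 bases on either side of the anchor; deletion and
inversion windows concatenate the *L*/2 bases upstream of the left
breakpoint with the *L*/2 bases downstream of the right breakpoint, so the
junction always sits at index *L*/2 and the rearranged interior is never
shown to the model. Windows that would cross a chromosome end or contain a
non-ACGT base are dropped, not padded. Positives (real SVs) are balanced
1:1 with negatives — either uniform background positions whose windows
avoid all known breakpoints, or, for deletions/inversions, simulated
events whose lengths are drawn from the empirical length distribution of
the positives and whose windows are built by the same flank-joining rule.
Splits are 60/20/20 with the test fraction rounded up first
(`ceil(0.2·n)`), then the validation fraction of the remainder; samples
sharing an anchor position always land in the same split.

## Models

The sequence model is a residual CNN: 1×1 convolution projecting the
4 one-hot channels (A,T,C,G order) to `stem_channels`, batch norm, ReLU;
`n_residual_blocks` blocks of [conv(k=11, p=5) → batch norm → ReLU →
conv(k=11, p=5) → skip add → ReLU]; a 1×1 convolution down to
`bottleneck_channels`; flatten (`L × bottleneck` units — 12,800 at the
reference configuration of 400 bp × 32 channels); a dense ReLU layer; and
a single sigmoid output. Training minimises binary cross-entropy with
AdamW (decoupled weight decay, applied to weight matrices only), halves
the learning rate after 3 epochs without validation improvement, stops
after 5 such epochs, and restores the weights of the best validation
epoch. "Improvement" means a strict decrease of at least 1e-5, to avoid
float jitter driving the schedule. The engine is pure NumPy: convolutions
are lowered to im2col matrix products so the arithmetic runs through
BLAS; all randomness (initialisation, batch order) comes from a seeded
`numpy.random.Generator`, making runs bit-reproducible at fixed thread
count.

The tabular models are scikit-learn estimators fitted on train+validation
rows: a 1000-tree random forest (balanced class weights, √p candidate
features per split, bootstrap resampling), an L2-penalised logistic
regression on standardised features, and an ensemble — the same forest
with the CNN's predicted probability appended as a feature. The CNN
probabilities fed to the ensemble come from the CNN trained on the
training split (early-stopped on validation); the mild optimism this
induces on validation rows is accepted as part of the protocol. AUROC is
computed from average ranks (the Mann–Whitney statistic; ties count ½)
and AUPRC as the step-wise sum Σ(Rᵢ−Rᵢ₋₁)·Pᵢ; both are cross-checked in
the tests against brute-force pairwise/threshold-sweep oracles and
scikit-learn.

## Annotation features

Counts (SNPs, small insertions/deletions, large insertion/deletion/
inversion breakpoints) are taken over the physical interval(s) the window
sequence came from — both flanks for junction windows. A window's own
SV contributes its breakpoints to nobody: neighbour counts exclude the
focal variant, since a self-counting feature would trivially separate the
classes. Distances (simple repeat, Alu, L1, exon) are 0 when the window
span overlaps an interval, otherwise the distance from the anchor(s) to
the nearest interval edge; chromosomes with no annotated interval yield a
large finite sentinel (1e9) so the feature table stays total. Conservation
is averaged with uncovered bases imputed as 0, alongside a coverage
fraction column.

## Perturbation analyses

All insertion analyses modify background windows and measure
Δp = p(modified) − p(original). Motif insertion splices the motif in and
trims the same side of the window back to length *L*, so the base at the
central coordinate keeps its index (insertions at the exact centre
necessarily displace it). Microhomology pairs place one k-mer ending at
centre−d and a second starting at centre+d (d uniform in
[1, L/2−k−1]), apply both before a single evaluation, and trim k bases
from each end; pair similarity is the positional identity fraction on the
forward strand, swept from identity to full mismatch. Saturation
mutagenesis substitutes each alternative base at every offset within ±30
of the centre; reference-base cells are exact zeros. G-quadruplex motifs
are four G-runs (≥3) with 1–7 nt loops; Z-DNA motifs are purine–pyrimidine
alternating dinucleotide chains (GC/CA/GT units joined so alternation
is preserved); both are compared against length-matched uniform-random
controls inserted at the same positions. k-mer enrichment uses
log2-ratio with pseudocount 1 and total-count normalisation, a two-sided
binomial test against the pseudocounted background proportion, and
Benjamini–Hochberg correction — the enrichment formula and test are
package conventions, as is the outlier rule in the gene-score correlation
(rank-regression residual above the 99th percentile). Permutation
importance is an in-package column-permutation loop (n=5 repeats, AUROC
on held-out data) with an injectable permutation hook for testing;
Jensen–Shannon divergence uses shared equal-width bins over the pooled
range, log base 2, via scipy's `jensenshannon` (squared), oracle-checked
against a direct two-term KL evaluation.

## The simulator

The generator emits a small multi-chromosome genome whose SV classes carry
exactly the determinants the models are supposed to learn:

* chromosomes of configurable length and GC (bases i.i.d. at the target
  GC; planted elements are drawn from the same composition so empirical
  GC stays within ±0.02 of target);
* planted annotation families: tandem simple repeats (2–5 bp units,
  80–160 bp), an Alu-like 300 bp consensus per chromosome with 5%-mutated
  copies, and a longer L1-like consensus with 5′-truncated copies;
* TE insertions whose target motif (default `TAAAA`) occupies positions
  −1…+3 relative to the breakpoint — making in-silico saturation
  mutagenesis recovery an exact test;
* deletions with an identical k-mer ending at the left breakpoint and
  beginning at the right breakpoint, so the flank-joined window contains
  a tandem homologous pair across the junction (default length: 8 bp
  point mass, within the 2–25 bp range of real microhomology);
* inversions with first breakpoints drawn from normal distributions
  around a few hotspot centres (sd 2 kb by default);
* simple-repeat deletions contained in planted repeat tracts;
* SNP/indel positions as per-base Bernoulli draws, 10× elevated within
  ±200 bp of any breakpoint by default;
* a conservation track at baseline 1.0 with −1.0 halos (±100 bp) around
  breakpoints, giving the conservation feature discriminative power;
* non-overlapping genes whose constraint score is
  `intercept − slope · (SV count within ±200 bp) + N(0, sd)` — a
  pLI-like score that rises with constraint — and per-SV allele
  frequencies Beta(1,2) at determinant-driven sites (TE insertions,
  microhomology deletions) versus Beta(0.2,2) elsewhere, creating a
  monotone AF–probability trend without asserting any real-world values.

Every planted determinant is written to a ground-truth manifest, and the
whole fixture serialises to FASTA(+fai)/VCF/BED/bedGraph/TSV/JSON that
round-trips losslessly through the package readers. What the simulator
does **not** emulate: realistic mutation-rate calibration, diploid
phasing, sequencing noise, long-range homology (segmental duplications),
or the correlated annotation structure of a real genome. Passing tests
therefore demonstrate that the machinery recovers planted signals, not
that real-genome effect sizes transfer.

## Desk-scale experiment sizes

The bundled experiments run on one CPU: fixtures of 1,000 positives
(3 × 400 kb chromosomes), 100 bp context windows, and a narrower network
(stem 48, bottleneck 16, hidden 64) trained with AdamW at lr 1e-3, batch
128, for 15–20 epochs. The reference-scale hyperparameters (400 bp,
128/32/128 channels, lr 5e-6) remain the defaults of `CNNSpec` and
`TrainConfig`; the reference learning rate is tuned for datasets three
orders of magnitude larger and barely moves a 2,000-sample run, so the
desk-scale runs raise it. Saturation mutagenesis averages 150 held-out
positive windows; insertion scans use 4–8 background windows with 5–50
positions; gene-level probabilities sample 30 positions in each of 200
genes.

## Known limitations

* The microhomology pair-insertion scan does not show a positive
  similarity trend on the desk-scale fixture model. The deletion-trained
  CNN learns the planted junction geometry essentially perfectly (test
  AUROC ≈ 0.99) and prefers identical over mismatched pairs when they are
  inserted adjacently at the junction (the geometry it was trained on),
  but the scan inserts pairs separated by 2d for d ≥ 1, and the small
  network trained on ~2,000 examples does not generalise homology
  detection across separations — its response gap exists only for d ≲ 3
  and is swamped by per-pair motif-content variance. A fixture with
  variable microhomology lengths (which would discourage the positionally
  rigid shortcut) is not learnable at all at this scale. Distance-general
  homology sensitivity evidently requires the reference-scale model and
  data diversity; the corresponding acceptance test is left failing
  rather than weakened, and the scan machinery itself is verified with an
  analytic homology-scoring model.
* Batch normalisation uses per-batch statistics during training, so
  predictions depend (reproducibly) on batch composition at training
  time; inference uses running statistics and is batch-invariant.
* Reverse-complement homology and strand symmetry are not modelled
  anywhere; all sequence comparisons are forward-strand.
* The repeat-class labelling rule assigns the dominant class whenever it
  covers ≥80% of the repetitive content, even if the repetitive content
  itself is a small fraction of the SV — the rule is applied literally.
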