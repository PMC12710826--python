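# svcontext

Predicting structural-variant (SV) susceptibility from local sequence
context and genomic annotations.

Structural variants — insertions, deletions and inversions ≥50 bp — do not
strike the genome uniformly: L1-endonuclease cleavage targets `T/AAAA`
motifs, microhomology-mediated repair leaves identical tracts at deletion
junctions, inversions cluster in hotspots, and simple repeats slip. This
package asks how much of that susceptibility is legible in a breakpoint's
immediate sequence neighbourhood, and provides the full modelling stack to
answer it:

* **Dataset construction** — 0-based windowing of VCF callsets against an
  indexed FASTA: a context window of length *L* (default 400 bp) centred on
  each breakpoint, with the interior of deletions/inversions omitted (the
  junction sits exactly at *L*/2), balanced against randomly sampled or
  breakpoint-structure-matched background windows; per-window annotation
  features (neighbouring SNV/indel/SV counts, GC, conservation, distances
  to simple repeats / Alu / L1 / exons, gene density); grouped 60/20/20
  splits with no genomic position shared across splits.
* **Models** — a residual 1-D CNN over one-hot (A,T,C,G) sequence
  (1×1 stem conv 4→128 → 2 residual blocks with kernel 11 / padding 5 →
  1×1 reduction to 32 channels → flatten (12,800 units at 400 bp) → dense
  128 → sigmoid), trained with binary cross-entropy, AdamW
  (lr 5·10⁻⁶, weight decay 10⁻³ at reference scale), reduce-on-plateau
  (factor 0.5, patience 3) and early stopping (patience 5), keeping the
  best-validation-loss weights; a 1000-tree balanced random forest; an
  L2 logistic baseline; and an ensemble forest that receives the CNN
  probability as an extra feature. Evaluation is rank-statistic AUROC and
  step-wise AUPRC. The network is implemented directly on NumPy
  (im2col convolutions), so everything runs on a plain CPU.
* **Interpretability** — k-mer enrichment and insertion scans (all 4⁵
  5-mers at random positions), symmetric microhomology pair insertions,
  G-quadruplex / Z-DNA motif effects against length-matched controls,
  in-silico saturation mutagenesis (±30 bp), Gini and permutation feature
  importances, Jensen–Shannon divergence of feature distributions, and
  Spearman correlation matrices.
* **Association** — allele-frequency strata (singleton / low /
  intermediate), gene-level mean predicted probability (30 random
  positions per gene), ±200 bp SV burden per gene, and Spearman
  correlations against per-gene constraint scores.
* **Synthetic-genome simulator** — a first-class module that plants each
  mechanistic determinant (TAAAA at positions −1…+3 of TE-insertion
  breakpoints, breakpoint-spanning microhomology at deletions, inversion
  hotspots, repeat-overlapping SVs, breakpoint-local SNP elevation,
  constraint scores anti-correlated with SV burden) with a ground-truth
  manifest, so every claim the models make can be checked against known
  truth at desk scale. Real callsets (e.g. population-scale VCFs against
  GRCh38) flow through the same readers.

## Worked example

```python
from svcontext.simulate import SimulationConfig, simulate_fixture
from svcontext.models import build_windows_and_features, train_model_bundle
from svcontext.cnn import CNNSpec, TrainConfig
from svcontext.interpret import ism
import numpy as np

cfg = SimulationConfig(seed=8, chrom_length=400_000,
                       n_sv_per_class={"te_insertion": 1000, "deletion_mh": 0,
                                       "simple_repeat": 0, "inversion": 0})
sim = simulate_fixture(cfg)
windows, table = build_windows_and_features(
    sim.reference, sim.records, sim.annotation_bundle(), 100, seed=8)
bundle = train_model_bundle(
    windows, table,
    CNNSpec(context_length=100, stem_channels=48,
            bottleneck_channels=16, hidden_units=64),
    TrainConfig(learning_rate=1e-3, batch_size=128, max_epochs=15, seed=8))
print({k: round(v.auroc, 3) for k, v in bundle.reports.items()})

test_sv = [w for w in windows if w.label == "sv" and w.split == "test"][:150]
m = ism(bundle.cnn, test_sv, radius=30)
print("ISM peak offset:", int(m.offsets[np.argmax(np.abs(m.matrix).max(axis=1))]))
```

prints (for seed 8; the equivalent seed-1 run is in `results/acceptance.json`)
AUROCs close to

```
{'cnn': 0.998, 'forest': 0.997, 'linear': 0.997, 'ensemble': 1.0}
ISM peak offset: 1
```

i.e. the sequence-only CNN separates planted TE-insertion breakpoints from
background almost perfectly, and saturation mutagenesis localises its
sensitivity inside the planted endonuclease motif footprint (−1…+3 around
the breakpoint).

The same pipeline is scriptable from a shell:

```
svcontext simulate --outdir fx --seed 42
svcontext build    --fixture fx --outdir run --context-length 100
svcontext train    --outdir run
svcontext interpret --outdir run --analysis ism
svcontext associate --fixture fx --outdir run
```

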