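# Methods

## The model

`scprofile` predicts single-cell genomic profiles — stranded scRNA-seq
read coverage and scATAC-seq Tn5 insertion counts — from DNA sequence, at
32-bp resolution. Two components interact:

1. **Sequence encoder.** A window of `input_length` base pairs is one-hot
   encoded (A, C, G, T channels; N is a zero column) and mapped to one
   embedding vector per 32-bp bin. Only the center `output_bins` bins are
   kept. At full scale the geometry constants are those of the large
   published profile predictors this package interoperates with: 524,288
   bp in, center 6,144 bins out (196,608 bp), embedding width 1,920. The
   encoder is a *contract*: any module producing `(output_bins, E)` from
   one-hot input can stand behind it. The package ships a desk-scale
   `MiniBackbone` (below); loading full-scale pretrained weights is an
   extension point, not a dependency.

2. **Cell-state decoder.** Each cell is represented by a low-dimensional
   multiomic embedding (default D = 14, the dimensionality produced by
   the usual multiome latent-variable models). A hypernetwork — an MLP
   with one hidden GELU layer — maps the cell embedding to the weights of
   that cell's 1×1 convolutional output filter: `(E+1, 2, 1)` for
   stranded RNA (E filter weights plus one bias per strand; 1,921 rows at
   full scale), `(E+1, 1, 1)` for unstranded ATAC. Decoding is
   position-wise: `out[c, s, b] = softplus(emb[b]·w[c, s] + bias[c, s])`.
   Softplus keeps profiles nonnegative; nothing mixes across bins, which
   is what makes exon-restricted decoding (`decode_region`) exactly equal
   to slicing the full decode.

Because the decoder is generated from the cell embedding rather than
being a per-cell output head, parameters do not grow with the number of
cells, and unseen cells with embeddings in the same latent space can be
decoded directly.

### Targets and the squashed scale

Training targets are built on the fly from a `CoverageStore`: per-cell
RNA alignment segments (split reads stored as one entry per aligned
block, strand-separated) and per-cell ATAC insertion events (two per
fragment, at the first and last covered base). Per 32-bp bin, the RNA
value is the summed per-base coverage and the ATAC value the insertion
count. Values are then variance-stabilized: ATAC is pre-scaled by 0.05
so both assays share a scale, values are power-compressed (`v**0.75`)
and soft-clipped above `clip_soft = 5`
(`v -> 5 + sqrt(v - 5)`). Inference inverts the transform exactly
(algebraic inverse; ATAC rescaled by 20). The round-trip is the identity
to better than 1e-6 relative error on nonnegative inputs.

### Loss

The objective is the standard profile-modeling composite: a Poisson term
on window totals plus a multinomial term on the positional distribution,
per track (sequence × cell × strand), averaged over tracks and assays.
`LossWeights` defaults to Poisson weight 0.2 / multinomial 1.0 — the
weighting of the large-scale reference implementation this loss follows.
The desk-scale preset (below) uses 1.0/1.0.

### Fine-tuning machinery (LoRA)

Linear and convolutional layers expose a *kind* (convolution,
attention-query, attention-value, mlp-projection). `inject_lora` adds
rank-`r` factors `B·A` (A small-random, B zero, scaling `alpha/rank`,
defaults rank 8, alpha = rank) to all targeted kinds and freezes base
weights; zero-initialized B makes injection exactly output-preserving.
`merge_lora` folds `scaling·B·A` back into the weights, restoring the
original parameter count with forward agreement to ≤1e-5. The training
engine trains only adapters, hypernetworks and the from-scratch
projection layer when adapters are present; with no adapters it trains
the whole backbone (the desk-scale, from-scratch mode).

## The mini backbone

The desk-scale encoder had to satisfy an unusual constraint: be fully
trainable on one CPU in minutes, on a fixture ~four orders of magnitude
smaller than the data full-scale encoders are pretrained on. Three
design choices follow from diagnostics on planted-motif recovery, and
deviate deliberately from a naive scaled-down copy of the big
architectures:

- **Wide stride-1 motif layer + max-pool downsampling.** Chains of
  strided convolutions washed out motif activations (a linear probe for
  planted-motif presence fell to chance after two layers). Convolving at
  full resolution and downsampling with non-overlapping max pooling
  preserves the peak response of a motif match. Pooling is applied
  before normalization/activation, which also halves the elementwise
  work.
- **Residual conv blocks and a global max-context block.** Residuals let
  first-layer detector channels survive the tower. The context block
  takes the per-channel *maximum* over bins (presence is a peak
  statistic; a mean over thousands of positions buries 2–4 motif
  occurrences below noise), passes it through a two-layer MLP and adds
  it to every bin — letting a regulatory element anywhere in the window
  modulate the whole profile, complementing the (single) transformer
  block with sinusoidal positions. A multiplicative gating variant
  (`ctx_mode="mul"`, squeeze-excite style) is available; additive
  context is the default as it trained no worse and keeps the block
  linear.
- **PWM-seeded first-layer filters.** A pretrained foundation encoder
  arrives with a motif vocabulary; the mini backbone stands in for such
  a model, so its first-layer filters can be seeded from a PWM set (both
  orientations; log-probability-shaped weights with a negative bias so a
  filter fires only near its consensus). De-novo motif discovery by SGD
  needs orders of magnitude more sequence than the fixture provides.
  What remains to be *learned* from reads — and what the tests actually
  check — is which motifs matter, for which gene, in which cell state,
  with what sign and magnitude, plus the placement of coverage on exons.

Per-position channel normalization is the default (training and
inference behave identically at any batch size); classic batch
normalization with running statistics, and the freeze-for-the-first-step
protocol of the full-scale recipe, remain implemented and tested.

## Training procedure

Per step, `batch_sequences` windows are drawn from the training split;
each is augmented by a ±3 bp shift (zero-padded edge) and, with
probability 0.5, reverse complementation — in which case the target
profiles are position-flipped and the RNA strand channels swapped. Per
window, `cells_per_sequence` cells are sampled without replacement.
AdamW (decoupled weight decay 1e-6, global gradient-norm clip 1.0)
optimizes two learning-rate groups — hypernetworks vs. backbone/adapters
— with linear warmup then linear decay. Full-scale defaults follow the
published recipe (batch 8 × 64 cells, 4e-4/2e-4, warmup 1,000 steps, 40
epochs); normalization layers are frozen and dropout disabled for the
first optimization step only. After every epoch the validation metric —
mean across cell types of the Pearson correlation between
log2(pseudobulk predicted + 1) and log2(pseudobulk observed + 1) gene
counts — is computed and the best checkpoint retained ("largest
correlation across cell types" is read as the mean across cell types;
the minimum is a stricter alternative).

At inference, predictions average the forward pass and the
position-flipped reverse-complement pass, then invert the squashed
scale. Expression counts sum the strand-matched RNA track over every
output bin overlapping an exon (a bin overlapping by ≥1 bp counts
fully — bin-level summation, not pro-rata); locus accessibility sums the
ATAC track over the whole output window.

## The synthetic multiome generator

The generator emulates the *structure* of 10x multiome data with fully
known truth:

- **Genome.** Random contigs carrying compact genes (2–4 exons of
  120–180 bp, introns 70–110 bp, both strands). Gene structure is
  imprinted on the sequence the way real genomes mark it: GC-elevated
  exons (0.58 vs 0.41 background), splice-site consensus at intron
  boundaries (strand-aware), a TATA-like element 28 bp upstream of the
  TSS. Without such signals coverage placement is unlearnable from
  sequence and only memorizable — an early version of the generator
  made that mistake.
- **Regulatory truth.** A toy PWM set (distinct 8-mer consensus motifs,
  consensus probability 0.94): one ubiquitous activator (planted in half
  the promoters; expression ×3, accessibility ×2 in all groups) and one
  group-specific activator per cell group (planted for 75% of genes,
  group uniform; ×6 expression, ×4 accessibility in the responsive group
  only). A chosen element is planted as several copies — one
  promoter-proximal slot plus one per intron — but its multiplier
  applies once; copies keep every exon within local sequence reach of
  the element, as promoter-proximal and intragenic binding sites do.
- **Cells.** 240 cells in 3 groups; 14-dimensional embeddings carrying
  2× the group one-hot plus Gaussian noise (linearly separable with a
  margin, like a well-fit multiome latent space); log-normal per-cell
  depth factors (σ = 0.3).
- **Reads.** RNA reads per (cell, gene) are Poisson with rate `2.0 ×
  motif multipliers × depth factor` (several reads per cell on active
  genes — the deep end of real single-cell data, chosen so desk-scale
  training sees signal); 80-bp reads placed on the mature transcript
  (splitting across junctions; a configurable single-exon fraction;
  optional exponential 3′ bias, off in the tiny preset). ATAC fragments
  concentrate at promoters with group-modulated rates plus a uniform
  background.
- **Variants.** For each group-specific element, the maximally
  score-reducing single-nucleotide substitution in one (intronic) copy,
  with the generative effect sign recorded; plus null variants in
  neutral sequence ≥100 bp from any planted site.

What passing tests on this fixture do and do not show: they demonstrate
that the full pipeline — extraction, transform, training, checkpoint
selection, inference, motif/variant scoring — recovers planted
regulatory structure end-to-end; they do not demonstrate performance on
real data, where motif grammar, chromatin context, and noise are far
richer, and where the method's published results rely on a large
pretrained encoder.

## The tiny preset (study conditions for the end-to-end tests)

24 contigs × 32,768 bp × 12 genes (288 genes); 20 training contigs, 2
validation, 2 test (held-out by contig — embeddings are not
leakage-filtered here because they are generated, not fitted). The 240
training genes matter: with fewer, per-window memorization is cheaper
for the optimizer than the shared motif→expression rule, and held-out
predictions carry no group structure. Model: 4,096-bp windows, 64
output bins, embedding width 32, 24 channels, one transformer block,
hypernetwork hidden width 48, first layer seeded with the fixture PWMs
plus splice/TATA elements. Training: 240 epochs × 16 steps of 4
sequences × 64 cells, learning rate 5e-3 (both groups), warmup 100
steps, Poisson/multinomial weights 1.0/1.0, and the final weights are
the average of the five best validation epochs (a stochastic
weight-averaging variant; k = 1 recovers plain best-epoch selection).
This runs in roughly a quarter hour on one CPU; problem sizes were
chosen so the whole train-evaluate-interpret cycle fits a desk machine.

Where this lands, honestly: on held-out contigs the per-group
across-gene count correlation against the generative truth reaches
roughly 0.5–0.9 depending on group and seed (validation was still
improving when the step budget ran out; doubling it lifts the mean but
two of three groups remain below 0.8). Variant-effect recovery is
strong (planted-site effect signs ~97% correct, null variants
~uniformly negligible). Motif-mutation scores are reliably negative in
the responsive group, but the separation from non-responsive groups is
inconsistent — the model's group-conditioning is only partially
disentangled at this training scale, so mutating one group's element
can still move another group's predictions. These are training-scale
limits of a from-scratch CPU model, not properties of the method, whose
published setting starts from a large pretrained encoder.

## Numerical choices

- All computation is float64 (deterministic CPU numerics); the GELU
  tanh is evaluated in float32 (absolute error ~1e-8, below the tanh
  approximation's own error) for speed.
- PWM scan p-values use exact dynamic programming over the
  per-position log-odds discretized at 1e-3; window scores are computed
  with the same discretized values so ties are handled exactly
  (otherwise a hit tied at the threshold can be assigned the tail
  probability of the next stricter score).
- Overlapping motif hits (including across strands) are merged into one
  span before random replacement.
- Deduplication keys: RNA (barcode, UMI, chrom, first-segment start),
  falling back to (barcode, chrom, segments) without UMI; ATAC
  (barcode, chrom, fragment).
- Insertion positions: fragment start and end−1 (last covered base);
  Tn5 shifts are assumed already applied upstream, and the convention
  is configurable at the fragment-parsing level rather than silently
  re-shifted.
- Degenerate cases return NaN with a warning rather than raising:
  zero-variance rows in correlation metrics, purely additive matrices
  in the deviation (double-centered) correlation, empty distance bins
  in sign-concordance tables.
- Ranking ties break lexicographically by cell-type name, making all
  deconvolution rankings deterministic.

## Known limitations

- The mini backbone is not a substitute for a pretrained encoder on
  real genomes; its motif vocabulary is seeded, not learned.
- The LoRA-adapter training path is exercised on unit scale; the
  end-to-end recovery run trains from scratch because a frozen *random*
  backbone has no pretrained features worth adapting.
- Exon-overlap counting is bin-level (full bin on ≥1 bp overlap), which
  slightly overcounts relative to per-base summation at exon edges;
  both sides of every comparison use the same convention.
- The profile-level correlation uses natural log (log2 for count
  metrics); both are exposed as options since conventions differ.
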