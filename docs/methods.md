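# Methods

`ribolens` re-creates, at configurable desk scale, a complete workflow for
discovering translation-associated RNA motifs in 5'UTRs with an
interpretable nucleotide language model. This note records the models and
procedures implemented, the parameters that matter, and the design choices
made where the design was genuinely open.

## Corpus curation

Transcripts are RNA sequences over {A,C,G,U} (T normalized to U on ingest)
with half-open genic-region intervals tiling the sequence in the order
5'UTR → CDS → 3'UTR. Curation applies, in order:

* rejection of records with non-ACGU characters (logged, not fatal);
* removal of records lacking region annotation (when required);
* truncation of sequences above **1,026 nt** and removal below **20 nt**.
  Truncation keeps the 5' end: the downstream tasks centre on 5'UTR and
  start-codon context, so the 3' overflow is the expendable side;
* redundancy removal at **80% identity** with a greedy longest-first
  clustering in the cd-hit-est style: a sequence joins the first existing
  representative whose best ungapped containment window reaches the
  threshold, otherwise founds a cluster. This is a documented
  reimplementation rather than a shell-out so the package is testable with
  no external binaries; identity is defined as the maximal match count of
  the shorter sequence slid along the longer, divided by the shorter
  length.

## Local structure annotation

Every curated sequence receives a dot-bracket annotation of *local*
secondary structure: no base pair may span more than **30 nt**
(`max_bp_span`), pairing is Watson-Crick plus G·U, and hairpin loops hold
at least 3 unpaired bases. The default engine is a deterministic
base-pair-maximization dynamic programme. Because all pairs are local, the
optimum decomposes into a chain of local blocks; the implementation runs a
banded interval DP over widths up to the span cap followed by a linear
chain DP, O(L·span²) with vectorized inner loops, and reproduces the
unrestricted interval-DP optimum exactly (tested against brute force).
A thermodynamic engine (RNAfold with `maxBPspan`) can be plugged in behind
the same `sequence → dot-bracket` interface when the ViennaRNA bindings
are available; the built-in engine is the default because it is
deterministic and dependency-free, which is what the motif machinery
needs from this stage.

## TE labelling from count tables

Given polysome and RNA-seq count tables and transcript lengths, RPKM is
computed per library (counts × 10⁹ / (library size × length)), genes below
RPKM 1 in either library are removed, TE = polysome RPKM / RNA-seq RPKM,
and binary labels are assigned at mean ± sd (sample sd, ddof = 1): high
(1) at or above mean + sd, low (0) at or below mean − sd, unlabelled
between. With identical tables the distribution is degenerate (sd = 0) and
nothing is labelled (warned). The mean ± sd rule presumes a unimodal TE
distribution with sparse tails; it is not meaningful for a cohort that is
mostly extreme.

## Tokenization and the corruption scheme

One token per nucleotide; special tokens `<cls> <pad> <eos> <unk> <mask>`
plus eight inert placeholder tokens reserved for modified bases. Sequences
are wrapped `<cls> … <eos>` (BERT-style; the placement is a convention,
not a claim). Per-token labels (structure classes `(`/`)`/`.` and region
classes 5'UTR/CDS/3'UTR) ride along with an ignore value at special
positions, excluded from every loss.

Masked-nucleotide corruption selects 20% of base positions per sequence
(round-half-away-from-zero), splits the selection 2:1:1 into
`<mask>` / random base / unchanged — i.e. 10% / 5% / 5% of the sequence —
with largest-remainder apportionment so the counts are exact per sequence,
and draws the random replacement uniformly from {A,C,G,U} (the original
base is not excluded). Selection, assignment and replacement all flow from
one seed.

## Model

An encoder-only transformer: token embedding (no absolute-position table),
`layers` pre-norm blocks (multi-head attention + GELU feed-forward,
residual connections, layer norm before each sublayer and a final layer
norm), rotary position embedding applied to queries and keys (half-split
convention, base 10,000), and four heads: per-position vocabulary logits
(masked-nucleotide modelling), 3-class structure logits, 3-class region
logits, and a 2-class sequence head. The reference scale is 12 layers /
24 heads / embedding 480 with a 4× feed-forward (≈33M parameters);
experiments here use configured-down instances. The feed-forward width
(unstated at reference scale) is set to 4× the embedding so the total
lands in the ≈35M range of the full-scale design.

The sequence head reads a masked mean over the unpadded token embeddings
rather than the `<cls>` embedding. The `<cls>` position receives no
gradient from any pretraining objective in this setup, and in desk-scale
experiments `<cls>`-read fine-tuning was markedly less stable (macro F1
0.76–0.88 across seeds, versus 0.85–0.89 for mean pooling on identical
data); `seq_pool="cls"` remains available.

Everything runs on an in-repo reverse-mode autodiff engine over NumPy
arrays (float32 by default for the model; the standalone loss functions
preserve float64 inputs). Inference uses a no-graph mode; training frees
each step's graph after backprop. Fused kernels exist for the affine map,
attention, GELU and layer norm; gradients are verified against finite
differences in the test-suite.

## Losses

* masked-nucleotide loss: mean negative log-likelihood over the selected
  positions only;
* structure and region losses: cross-entropy over counted positions,
  reported in the summed form; a per-position mean is also exposed and is
  what the training loop optimizes so the three objectives stay on
  comparable scales regardless of sequence length;
* the pretraining loss is the weighted sum of the three (default weights
  1,1,1).

## Training loops

Pretraining draws a random batch and a fresh corruption each step (dynamic
masking), optimizes with AdamW (lr 10⁻³, weight decay 0.01, 5% linear
warmup), and logs the per-component trajectory; everything is
deterministic given the seed on a single device.

Fine-tuning covers sequence-level TE classification (from 5'UTRs) and
token-level genic-region annotation. Datasets are redundancy-filtered at
80% identity *before* splitting so no test sequence has a near-duplicate
in training; the split is stratified 80/20, and a validation slice (15% of
the training side) is the early-stopping monitor: training stops when the
best validation macro F1 has not improved for `patience` epochs (reference
schedule 100 epochs / patience 30; desk scale uses smaller budgets), the
best-validation state is restored, and the reported F1 comes from the
untouched test split. Monitoring the test split directly would inflate the
background model's apparent F1 by selection bias — the max over ~20 noisy
evaluations of a chance-level quantity sits well above 0.5.

The background model is trained identically on the same dataset with the
label vector permuted (permutation rather than independent resampling
keeps the class balance, so chance level stays interpretable). A
three-replicate helper reports mean ± sd of F1 across fine-tuning seeds.

## Attention contrast

Attention maps (layers × heads × L × L per sequence) from the true and
background models are averaged over layers and heads, subtracted
(true − background; the direction follows the narrative "subtract the
background from the true model" — the provenance dict records it), and
negatives are clamped to zero. The per-position score is the column mean
of the clamped matrix: the average contrast attention a position
*receives*. The row/column choice is a design decision recorded in the
provenance; scores are computed after stripping `<cls>`/`<eos>`.

Cohort z-scores use the mean and sd pooled over every position of every
sequence. Both calling thresholds are exposed: 2.576 (two-sided 1%) and
2.326 (one-sided 1%), as standard-normal quantiles.

The AUG-anchored meta-profile averages per-position scores at offsets
−window…−1 upstream of the start codon (offset −1 = last 5'UTR base);
sequences shorter than the window contribute what they have. Sequence-logo
information content is IC = 2 − H (bits) per position.

## Motif discovery chain

1. **Seed library**: exhaustive enumeration of perfect hairpins in 5'UTRs
   with stem 4–7 bp, loop 4–9 nt, total ≤ 30 nt, Watson-Crick + G·U
   pairing. This is the built-in "all suboptimal foldings" mode — at ≤30 nt
   every geometry-admissible fold is enumerable, so no thermodynamic
   enumeration is needed; identical (sequence, structure) motifs at
   different locations are occurrences of one library entry.
2. **Attention association**: for each motif with ≥3 usable occurrences, a
   two-sided paired t-test of (mean contrast inside the occurrence
   footprint) vs (mean over the rest of the same 5'UTR), one pair per
   occurrence. What the two members of the pair should be is not specified
   by the procedure the package follows; this inside/outside design is the
   package's choice and is stated prominently here. Degenerate cases
   (identical differences) report p = 0 with a flag, or p = 1 when all
   differences are zero.
3. **Multiple testing**: Benjamini–Hochberg step-up; motifs with q < 0.01
   and positive mean difference are the high-attention set.
4. **Clustering**: one-hot encoding (4 base channels + a paired-position
   channel per position, left-aligned, zero-padded), Ward linkage on
   Euclidean distance, dendrogram cut at every k in 2..100; clusters with
   ≥30 members are kept, deduplicated on identical member sets across cuts.
5. **TE association**: two-sided Fisher's exact test on (cluster members
   in high/low-TE hosts) vs (non-member significant-seed occurrences in
   high/low); occurrences, not unique transcripts, are counted
   (configurable choice). Odds ratio > 1 with p < 0.05 ⇒
   high-translation-associated; < 1 ⇒ low. Zero-margin tables are
   undefined and the cluster is dropped with a reason.
6. **Information filter**: average positional information content (APIC,
   mean of per-position IC over left-aligned members) must be ≥ 1.5 bits.
7. **rG4s**: a built-in scanner (≥4 tracts of ≥2 G, loops 1–7 nt — two or
   more stacked quartets) replaces any external database. Occurrences of
   one rG4 sequence across transcripts form one paired test (a paired
   t-test on a single occurrence is undefined); BH runs independently
   within each rG4 length stratum; q < 0.01 with positive difference is
   reported, with GGA/GGU repeat character flagged.

## Synthetic study design

The generator replaces any external corpus and defines the study
conditions. Defaults: 400 transcripts; 5'UTR 30–48 nt, CDS 24–42 nt
(AUG-anchored), 3'UTR 6–12 nt; uniform base composition; 2% label-flip
noise; one seed drives everything.

Four motif classes are planted (ledger-recorded ground truth):

| class | motif | effect (log-odds) | prevalence |
|---|---|---|---|
| Kozak-like context | `ACAACCAACA` consensus at offsets −10…−1 | +6 | 0.40 (independent) |
| GC-stem hairpin | `GCGC AAAA GCGC` | −20 | 0.30 |
| mixed-stem hairpin | `ACGU AAAA ACGU` | +6 | 0.30 |
| rG4 | `GGAGGAGGAGG` | −20 | 0.26 |

The Kozak-like context is a composition bias, not an invariant string:
each planted copy is drawn PWM-like around the consensus with 30% per-base
divergence, as a real initiation context would be (a fixed 10-mer repeated
in 40% of transcripts becomes a pretraining attention magnet for the
background model, which inverts the contrast there).

Structural classes are mutually exclusive (a 5'UTR this short holds one
structural motif); the AUG context is drawn independently. Labels are
Bernoulli(sigmoid(sum of effects)). Three deliberate features make the
study identify the mechanism rather than a shortcut:

* **Veto effects.** The repressive motifs dominate (−20 vs +6), so a
  repressive structure keeps a transcript low-TE even when a promoting
  motif co-occurs. Without this, high/low would be decidable from the
  promoting motifs alone and a classifier would never need to attend to
  the repressive ones — early experiments showed exactly that failure:
  the sign of the attention contrast at low-TE motifs was unstable
  run-to-run when the classes were mutually exclusive.
* **Boundary caps.** Insertions carry single-A flanks so random context
  cannot extend a planted stem or G-tract; without caps the rG4 matches
  fragment across length strata and lose test power.
* **Decoys.** Effect-free insertions — sub-threshold G-tract fragments
  (`GGAGG`, 50% of non-rG4 transcripts) and correctly-spelt but mispositioned
  Kozak-like copies (30% of non-carriers) — make base composition alone
  non-discriminative, so the classifier must recognize motif arrangement
  and position. Without the G-tract decoys a mean-pooled classifier can
  separate rG4 carriers by G-content with no attention shift at all, and
  the contrast signal at rG4s vanishes.

Count tables are negative-binomial with polysome/RNA ratio 4.0 (high),
0.25 (low), 1.0 (typical), lognormal jitter at the configured dispersion
(default 0.05), a lognormal expression distribution, and a configurable
fraction of near-zero-expression genes for the RPKM filter to remove.

What the generator does **not** emulate: real codon usage and base
composition, splice isoforms, degenerate motif families (mutation rates
are configurable but default to 0), correlated expression structure, and
any coupling between structure and expression. Passing recovery tests
therefore show that the pipeline's statistics and mechanics work when the
causal story is as modelled — not that the model would find motifs in any
particular real transcriptome.

## Desk-scale recovery study

`run_recovery_study` executes the whole workflow with a tiny encoder
(2 layers, 4 heads, dim 64, feed-forward 128). Problem sizes are the
package's desk-scale choices: a 400-transcript corpus, 2,000 pretraining
steps (batch 16), fine-tuning ≤70 epochs (patience 22, lr 1.5×10⁻³,
batch 24) for the true and background models. Because pretraining is
label-free, one foundation checkpoint may be shared across seeded
fine-tune/discovery runs (`checkpoint=` argument), which is how the
repeated-seed tests amortize it. `assess_recovery` compares the discovery
output with the plant ledger: reported clusters are attributed to the
plant class they dominantly overlap (a coarse k = 2 cut can produce a
mixture cluster spanning both hairpin plants; it belongs to neither),
rG4 recovery requires a q < 0.01 hit overlapping a planted span with
mostly low-TE hosts, and the Kozak channel requires the meta-profile
maximum inside the planted offset band plus significantly elevated
in-band contrast for carriers.

## Numerical notes and limitations

* All randomness flows through `numpy.random.default_rng` seeds; repeated
  runs with one seed are bit-identical on one platform.
* The engine is CPU-only and single-device; at reference scale (35M
  parameters) it would be impractically slow — the reference configuration
  exists for parameter accounting, not training.
* Attention contrast at desk scale is a small signal on a noisy clamped
  difference; the paired design over many occurrences is what makes it
  testable. Single-occurrence motifs are untestable by construction
  (skipped with a reason).
* The 2–100 cluster sweep reports clusters from every cut; consolidation
  across cuts is deduplication on member sets only.

## Known limitation: the AUG-context channel at desk scale

Across every configuration tested, the Kozak-context channel of the
recovery study is unreliable at this scale while the structural channels
are robust. The structural hairpins and the rG4 are recovered with the
correct direction in essentially every seeded run; the AUG-proximal
sequence context usually is not: the meta-profile does not reproducibly
peak in the planted band, and carriers' in-band contrast is as often
depressed as elevated. Three causes were identified experimentally:
(i) the context is only weakly pivotal for the label (it decides the
outcome only for transcripts without a structural motif), so the
classifier earns little from attending to it; (ii) a short model can
classify such a feature through its value pathway with no measurable
attention shift; and (iii) the background model's pretrained attention is
itself drawn to frequent low-entropy content near the sequence boundary,
which pushes the clamped contrast negative. Making the context PWM-like
softens (iii) but does not overcome (i) and (ii). The corresponding
sub-check of the end-to-end recovery test therefore fails in most seeded
runs; it is kept as an honest negative result rather than weakened, and
the per-run breakdown is printed by the test on failure.
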