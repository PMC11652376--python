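# ribolens

An interpretable nucleotide language model toolkit for discovering
translation-associated RNA motifs in 5'UTRs — sequence contexts,
secondary-structure hairpins, and RNA G-quadruplexes (rG4s) — from paired
true/background attention contrast, with a synthetic-transcriptome
generator that makes the entire workflow testable end to end on one CPU.

It is aimed at computational RNA biologists who want to study *how* a
small encoder language model localizes regulatory elements: every stage —
corpus curation, self-supervised pretraining, fine-tuning on
translation-efficiency (TE) labels, attention attribution, and the motif
statistics — is an importable, seeded, deterministic library component.

## The method

**Curation.** Transcripts (5'UTR/CDS/3'UTR annotated) are truncated to
1,026 nt, filtered below 20 nt, redundancy-reduced at 80% identity
(greedy, cd-hit-est style), and annotated with *local* secondary structure
(no pair spanning > 30 nt; built-in base-pair-maximization folder, or
RNAfold behind the same interface). TE labels come from polysome/RNA-seq
count tables: RPKM ≥ 1 in both libraries, TE = polysome / RNA level,
binarized at mean ± sd.

**Model.** An encoder-only transformer with single-nucleotide tokens,
rotary position embedding, and three self-supervised objectives:

* masked-nucleotide modelling — 20% of bases per sequence corrupted
  (10% `<mask>`, 5% random base, 5% kept), with
  `L_MNM = −(1/|m|) Σ_{i∈m} log p_θ(x_i | x\i)`;
* secondary-structure prediction over classes {'(', ')', '.'}:
  `L_SSP = −Σ_i Σ_c y_{i,c} log p(y_{i,c}|x;θ)`;
* genic-region prediction over {5'UTR, CDS, 3'UTR}, same cross-entropy
  form.

The reference configuration (12 layers, 24 heads, embedding 480, ≈33M
parameters) is configurable down to desk scale. No PyTorch: the model runs
on a compact reverse-mode autodiff engine over NumPy included in the
package.

**Interpretation.** Two models are fine-tuned on 5'UTR TE labels: the true
model on real labels and a background model on permuted labels. Attention
is averaged over layers and heads, subtracted (true − background), and
clamped at zero; the column mean gives a per-position importance score.
Scores are standardized across the cohort (z > 2.576 two-sided-1% or
z > 2.326 one-sided-1% calls high-attention positions), profiled against
distance from the AUG, and summarized as sequence-logo information
content.

**Motif statistics.** Hairpin seeds (stems 4–7 bp, loops 4–9 nt, ≤ 30 nt)
are enumerated exhaustively from 5'UTRs; each seed's occurrences are
tested by a paired t-test of contrast inside the footprint vs the rest of
the UTR, Benjamini–Hochberg corrected (significant at q < 0.01).
Significant seeds are one-hot encoded, Ward-clustered at every cut
k = 2..100; clusters with ≥ 30 members are tested for TE direction by
two-sided Fisher's exact test (odds ratio > 1 and p < 0.05 ⇒
high-translation-associated) and filtered at average positional
information content ≥ 1.5 bits. rG4s (≥ 4 tracts of ≥ 2 G, loops 1–7 nt)
are scanned directly, scored with the same paired design, and
BH-corrected within each length stratum (q < 0.01).

## Worked example

`examples/03_finetune_te.py` builds 300 synthetic 5'UTRs whose TE label is
fully determined by a planted hairpin (`GCGCAAAAGCGC`), pretrains a small
encoder on them, and fine-tunes it twice:

```
$ python examples/03_finetune_te.py
true-label model:     macro F1 = 0.950 (n_test = 60)
shuffled-label model: macro F1 = 0.482
```

The true-label model recovers the planted determinant almost perfectly on
the held-out split, while the same architecture trained on permuted labels
sits at chance — the gap is the evidence that the model learned
label-linked sequence features, and the paired construction is what the
attention-contrast analysis builds on. `examples/04_attention_motifs.py`
runs the full discovery chain (pretrain → paired fine-tuning → contrast →
clustering → Fisher/APIC → rG4 scoring) on a 400-transcript synthetic
corpus with four planted motif classes and prints the recovered clusters
with their direction, odds ratio and information content.

The other examples cover corpus generation and curation (`01`), the three
pretraining objectives (`02`), and the rG4 scanner alone (`05`). A thin
CLI (`ribolens synth|curate|pretrain|finetune`) wraps the shell-facing
stages.

## Layout

```
src/ribolens/
  corpus.py      curation, identity clustering, TE labelling
  io.py          FASTA / region TSV / GFF3 / dot-bracket / count tables
  folding.py     span-constrained folding engines
  tokenizer.py   single-nucleotide vocabulary, masking scheme
  _autodiff.py   reverse-mode autodiff over NumPy
  model.py       rotary-embedding encoder + the three losses
  training.py    pretraining, fine-tuning, background models, metrics
  interpret.py   attention contrast, z calling, meta-profiles, logo IC
  motifs.py      seed library, paired tests, BH, clustering, Fisher, rG4
  synthdata.py   synthetic transcriptomes with planted causal motifs
  pipeline.py    end-to-end recovery study and ground-truth assessment
  cli.py         thin command-line interface
```
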