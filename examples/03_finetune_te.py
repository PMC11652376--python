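"""Fine-tune on translation-efficiency labels: true vs shuffled labels.

A dataset whose labels are fully determined by a planted hairpin 12-mer is
classified nearly perfectly by a model fine-tuned from a short
self-supervised pretraining pass, while the same architecture trained on
permuted labels stays at chance — the paired true/background construction
underlying the attention-contrast analysis.
"""

import numpy as np

from ribolens import FinetuneSpec, ModelConfig, finetune, pretrain
from ribolens.corpus import GenicRegions, TEDataset, TEEntry, TranscriptRecord
from ribolens.folding import annotate_local_structure

MOTIF = "GCGCAAAAGCGC"
rng = np.random.default_rng(0)

entries = []
for i in range(300):
    label = i % 2
    while True:
        seq = "".join(rng.choice(list("ACGU"), 32))
        if MOTIF not in seq:
            break
    if label:
        pos = int(rng.integers(0, 32 - len(MOTIF)))
        seq = seq[:pos] + MOTIF + seq[pos + len(MOTIF):]
    entries.append(TEEntry(f"g{i}", 4.0 if label else 0.25, label, seq))
dataset = TEDataset(entries, 2.1, 1.9)

records = []
for e in entries:
    n = len(e.utr5)
    r = TranscriptRecord(e.id, e.utr5,
                         GenicRegions((0, n // 2), (n // 2, n), (n, n)))
    r.structure = annotate_local_structure(r.sequence, 30)
    records.append(r)

config = ModelConfig(layers=2, heads=4, embed_dim=64, ffn_dim=128,
                     context_len=64)
checkpoint = pretrain(records, config, steps=600, seed=0, batch_size=16)

spec = FinetuneSpec(max_epochs=40, patience=15, seed=0, lr=1.5e-3,
                    batch_size=24)
_, true_report = finetune(checkpoint, dataset, spec)
print(f"true-label model:     macro F1 = {true_report.f1:.3f} "
      f"(n_test = {true_report.n_test})")

spec_bg = FinetuneSpec(max_epochs=15, patience=10, seed=0, lr=1.5e-3,
                       batch_size=24, label_mode="shuffled")
_, bg_report = finetune(checkpoint, dataset, spec_bg)
print(f"shuffled-label model: macro F1 = {bg_report.f1:.3f}")
# The gap between the two F1 scores is the evidence that the true model
# learned sequence features linked to the labels rather than dataset quirks.
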