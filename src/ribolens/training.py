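"""Pretraining and fine-tuning loops, metrics, and background models.

Pretraining optimizes the three self-supervised objectives jointly
(masked-nucleotide reconstruction, per-base secondary-structure class,
per-base genic-region class) with dynamic masking: corruption is redrawn
every step from the step index and the run seed.

Fine-tuning covers the two downstream tasks: sequence-level TE
classification from the 5'UTR (reading the <cls> embedding) and token-level
genic-region annotation. Datasets are redundancy-filtered at 80% identity
*before* the train/test split to prevent leakage, the split is stratified,
and early stopping retains the best-macro-F1 checkpoint with a patience
counter. The background model is trained identically but on permuted labels
(permutation preserves class balance, which keeps the chance-level F1
interpretable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import _autodiff as ad
from .corpus import TEDataset, TEEntry, TranscriptRecord, identity_cluster
from .model import ModelConfig, RNAEncoder, loss_cls, loss_mnm, loss_ssp
from .tokenizer import DEFAULT_VOCAB, IGNORE, MaskingPlan, apply_mnm_mask, encode

log = logging.getLogger(__name__)


@dataclass
class Checkpoint:
    """Model weights plus provenance; saveable as a single .npz archive."""

    config: ModelConfig
    state: dict[str, np.ndarray]
    trajectory: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_model(self, dtype=np.float32) -> RNAEncoder:
        m = RNAEncoder(self.config, seed=0, dtype=dtype)
        m.load_state_dict(self.state)
        return m

    def save(self, path) -> None:
        import json

        cfg = json.dumps(
            {**self.config.__dict__, "manifest": self.manifest}, default=str
        )
        np.savez_compressed(path, __config__=np.array(cfg), **self.state)


@dataclass
class FinetuneSpec:
    """Fine-tuning schedule and task selection.

    The full-scale schedule is 100 epochs with early stopping once the best
    F1 has not improved for 30 epochs; smaller budgets are used for the
    desk-scale experiments.
    """

    task: Literal["te_classification", "region_annotation"] = "te_classification"
    max_epochs: int = 100
    patience: int = 30
    seed: int = 0
    label_mode: Literal["true", "shuffled"] = "true"
    batch_size: int = 24
    lr: float = 1e-3
    test_fraction: float = 0.2
    val_fraction: float = 0.15  # of the train split; early-stop monitor
    identity_threshold: float = 0.8
    warmup_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class EvalReport:
    f1: float
    precision: float
    recall: float
    per_class: dict[int, dict[str, float]]
    n_test: int
    seed: int = 0


def macro_f1(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """Unweighted mean over observed label classes of per-class F1."""
    return evaluate(predictions, labels).f1


def evaluate(predictions, labels, seed: int = 0) -> EvalReport:
    """Per-class precision/recall/F1 and their macro averages.

    Classes are those observed in the true labels; a class never predicted
    gets precision 0 by convention.
    """
    preds = np.asarray(predictions)
    labs = np.asarray(labels)
    if len(preds) != len(labs) or len(labs) == 0:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    per: dict[int, dict[str, float]] = {}
    for cls in np.unique(labs):
        tp = int(np.sum((preds == cls) & (labs == cls)))
        fp = int(np.sum((preds == cls) & (labs != cls)))
        fn = int(np.sum((preds != cls) & (labs == cls)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[int(cls)] = {"precision": prec, "recall": rec, "f1": f1}
    macro = {k: float(np.mean([d[k] for d in per.values()])) for k in
             ("precision", "recall", "f1")}
    return EvalReport(macro["f1"], macro["precision"], macro["recall"], per,
                      len(labs), seed)


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------


def _batch_encode(records: Sequence[TranscriptRecord], pad_id: int):
    encs = [encode(r.sequence, r.structure, r.regions) for r in records]
    L = max(len(e) for e in encs)
    ids = np.full((len(encs), L), pad_id, dtype=np.int64)
    struct = np.full((len(encs), L), IGNORE, dtype=np.int64)
    region = np.full((len(encs), L), IGNORE, dtype=np.int64)
    mask = np.zeros((len(encs), L), dtype=np.int64)
    for i, e in enumerate(encs):
        n = len(e)
        ids[i, :n] = e.token_ids
        struct[i, :n] = e.structure_labels
        region[i, :n] = e.region_labels
        mask[i, :n] = 1
    return encs, ids, struct, region, mask


def pretrain(
    records: Sequence[TranscriptRecord],
    model_config: ModelConfig,
    steps: int = 1000,
    seed: int = 0,
    batch_size: int = 24,
    lr: float = 1e-3,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask_rate: float = 0.2,
) -> Checkpoint:
    """Pretrain from scratch on a curated corpus; returns a checkpoint.

    Deterministic given the seed on a single device. Each step draws a
    random batch and a fresh corruption; the per-step loss components are
    logged in the checkpoint trajectory. Structure/region losses use the
    per-position mean so the three objectives are on comparable scales
    regardless of sequence length (the canonical summed forms are available
    from the loss functions directly).
    """
    if not records:
        raise ValueError("empty corpus")
    model = RNAEncoder(model_config, seed=seed)
    opt = ad.AdamW(model.parameters(), lr=lr, weight_decay=0.01)
    rng = np.random.default_rng(seed)
    encs, ids, struct, region, attn = _batch_encode(records, DEFAULT_VOCAB.pad_id)
    n = len(records)
    trajectory = []
    warmup = max(1, int(0.05 * steps))
    for step in range(steps):
        take = rng.choice(n, size=min(batch_size, n), replace=False)
        bids = ids[take].copy()
        sel_p, sel_t, sel_b = [], [], []
        for row, src in enumerate(take):
            corr, plan = apply_mnm_mask(
                encs[src], mask_rate, seed=int(rng.integers(2**31))
            )
            bids[row, : len(corr)] = corr
            sel_p.append(plan.selected)
            sel_t.append(plan.targets)
            sel_b.append(np.full(len(plan.selected), row))
        plan = MaskingPlan(
            np.concatenate(sel_p), {}, np.concatenate(sel_t), seed
        )
        batch_idx = np.concatenate(sel_b)

        out = model.forward(bids, attn[take])
        comps = {}
        loss = None
        if weights[0]:
            t = loss_mnm(out.mnm_logits, plan, batch_idx)
            comps["mnm"] = t.item()
            loss = weights[0] * t
        if weights[1]:
            t = loss_ssp(out.ssp_logits, struct[take], reduction="mean")
            comps["ssp"] = t.item()
            loss = t * weights[1] if loss is None else loss + weights[1] * t
        if weights[2]:
            t = loss_cls(out.region_logits, region[take], reduction="mean")
            comps["cls"] = t.item()
            loss = t * weights[2] if loss is None else loss + weights[2] * t
        comps["total"] = loss.item()
        trajectory.append(comps)
        opt.zero_grad()
        loss.backward()
        opt.step(lr=lr * min(1.0, (step + 1) / warmup))
    return Checkpoint(
        model_config,
        model.state_dict(),
        trajectory,
        manifest={"seed": seed, "steps": steps, "lr": lr, "batch_size": batch_size,
                  "mask_rate": mask_rate, "objective_weights": list(weights)},
    )


# ---------------------------------------------------------------------------
# background datasets and fine-tuning
# ---------------------------------------------------------------------------


def make_background_dataset(dataset: TEDataset, seed: int = 0) -> TEDataset:
    """Random-label control: permute the label vector across entries.

    Permutation (rather than independent resampling) preserves the class
    balance, so a balanced-accuracy of ~0.5 is the expected chance level.
    """
    labelled = dataset.labelled
    if not labelled:
        raise ValueError("dataset has no labelled entries")
    rng = np.random.default_rng(seed)
    labels = np.array([e.label for e in labelled])
    perm = rng.permutation(labels)
    entries = [
        TEEntry(e.id, e.te, int(lab), e.utr5) for e, lab in zip(labelled, perm)
    ]
    return TEDataset(entries, dataset.mean, dataset.sd)


def _pad_ids(encs, pad_id: int):
    L = max(len(e) for e in encs)
    ids = np.full((len(encs), L), pad_id, dtype=np.int64)
    mask = np.zeros((len(encs), L), dtype=np.int64)
    for i, e in enumerate(encs):
        ids[i, : len(e)] = e.token_ids
        mask[i, : len(e)] = 1
    return ids, mask


def finetune(
    checkpoint: Checkpoint,
    dataset,
    spec: FinetuneSpec,
) -> tuple[RNAEncoder, EvalReport]:
    """Fine-tune a pretrained checkpoint on a downstream task.

    ``dataset`` is a :class:`TEDataset` for ``te_classification`` (labelled
    entries with 5'UTR sequences) or a list of annotated
    :class:`TranscriptRecord` for ``region_annotation``. Returns the model
    restored to its best-F1 epoch and the held-out evaluation report.
    """
    if spec.task == "te_classification":
        return _finetune_te(checkpoint, dataset, spec)
    return _finetune_regions(checkpoint, dataset, spec)


def _split(items, labels_for_strat, spec: FinetuneSpec):
    """Identity-filter, then stratified train/val/test index split.

    The validation split (carved from the training side) is the
    early-stopping monitor; the test split is touched only by the final
    report, so the retained-best-epoch selection does not bias it.
    """
    seqs = [s for s, _ in items]
    reps = identity_cluster(seqs, spec.identity_threshold)
    items = [items[i] for i in reps]
    y = np.array([labels_for_strat[i] for i in reps])
    idx = np.arange(len(items))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=spec.test_fraction,
        random_state=spec.seed,
        stratify=y,
    )
    if spec.val_fraction > 0:
        train_idx, val_idx = train_test_split(
            train_idx,
            test_size=spec.val_fraction,
            random_state=spec.seed + 1,
            stratify=y[train_idx],
        )
    else:
        val_idx = test_idx
    return items, train_idx, val_idx, test_idx


def _run_epochs(model, spec, n_train, train_step, val_fn, test_fn):
    """Shared epoch loop: early stopping on best validation macro F1.

    The model is restored to its best-validation epoch and the returned
    report is computed on the untouched test split.
    """
    opt = ad.AdamW(model.parameters(), lr=spec.lr, weight_decay=0.01)
    rng = np.random.default_rng(spec.seed)
    best_f1, best_state, best_epoch = -1.0, None, -1
    history = []
    steps_per_epoch = max(1, int(np.ceil(n_train / spec.batch_size)))
    total_steps = spec.max_epochs * steps_per_epoch
    warmup = max(1, int(spec.warmup_fraction * total_steps))
    step = 0
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n_train)
        for s in range(steps_per_epoch):
            take = order[s * spec.batch_size : (s + 1) * spec.batch_size]
            if len(take) == 0:
                continue
            loss = train_step(take)
            opt.zero_grad()
            loss.backward()
            step += 1
            opt.step(lr=spec.lr * min(1.0, step / warmup))
        report = val_fn()
        history.append(report.f1)
        if report.f1 > best_f1:
            best_f1, best_epoch = report.f1, epoch
            best_state = model.state_dict()
        if epoch - best_epoch >= spec.patience:
            log.info("early stop at epoch %d (best val %.3f @ %d)",
                     epoch, best_f1, best_epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    final = test_fn()
    final.seed = spec.seed
    return model, final, history


def _finetune_te(checkpoint, dataset: TEDataset, spec: FinetuneSpec):
    if spec.label_mode == "shuffled":
        dataset = make_background_dataset(dataset, seed=spec.seed)
    entries = [e for e in dataset.labelled if e.utr5]
    if not entries:
        raise ValueError("no labelled entries with 5'UTR sequences")
    labels_all = [e.label for e in entries]
    if len(set(labels_all)) < 2:
        raise ValueError("need both TE classes to fine-tune")
    items = [(e.utr5, e.label) for e in entries]
    items, train_idx, val_idx, test_idx = _split(items, [l for _, l in items], spec)

    model = checkpoint.to_model()
    vocab = encode("A").vocab
    encs = [encode(s) for s, _ in items]
    ids, attn = _pad_ids(encs, vocab.pad_id)
    y = np.array([l for _, l in items])

    def train_step(take):
        sel = train_idx[take]
        out = model.forward(ids[sel], attn[sel])
        return _seq_ce(out.seq_logits, y[sel])

    def eval_on(idx):
        with ad.no_grad():
            out = model.forward(ids[idx], attn[idx])
        preds = out.seq_logits.data.argmax(axis=-1)
        return evaluate(preds, y[idx], seed=spec.seed)

    model, report, history = _run_epochs(
        model, spec, len(train_idx), train_step,
        lambda: eval_on(val_idx), lambda: eval_on(test_idx),
    )
    return model, report


def _seq_ce(logits, labels):
    lp = logits.log_softmax(axis=-1)
    picked = lp[np.arange(len(labels)), np.asarray(labels)]
    return -picked.mean()


def _finetune_regions(checkpoint, records: Sequence[TranscriptRecord],
                      spec: FinetuneSpec):
    recs = [r for r in records if r.regions is not None]
    if not recs:
        raise ValueError("no annotated records")
    # stratify by majority region class of each transcript
    encs = [encode(r.sequence, None, r.regions) for r in recs]
    strat = [int(np.bincount(e.region_labels[e.region_labels != IGNORE],
                             minlength=3).argmax()) for e in encs]
    items = [(r.sequence, i) for i, r in enumerate(recs)]
    reps = identity_cluster([r.sequence for r in recs], spec.identity_threshold)
    recs = [recs[i] for i in reps]
    encs = [encs[i] for i in reps]
    strat = [strat[i] for i in reps]
    idx = np.arange(len(recs))
    try:
        train_idx, test_idx = train_test_split(
            idx, test_size=spec.test_fraction, random_state=spec.seed,
            stratify=strat)
    except ValueError:  # a stratum with a single member
        train_idx, test_idx = train_test_split(
            idx, test_size=spec.test_fraction, random_state=spec.seed)
    if spec.val_fraction > 0 and len(train_idx) >= 10:
        train_idx, val_idx = train_test_split(
            train_idx, test_size=spec.val_fraction, random_state=spec.seed + 1)
    else:
        val_idx = test_idx

    if spec.label_mode == "shuffled":
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(len(encs))
        region_labels = [encs[p].region_labels for p in perm]
        # permuted label vectors may differ in length; crop/pad to fit
        fixed = []
        for e, lab in zip(encs, region_labels):
            v = np.full(len(e), IGNORE, dtype=np.int64)
            n = min(len(e), len(lab))
            v[:n] = lab[:n]
            fixed.append(v)
        region_labels = fixed
    else:
        region_labels = [e.region_labels for e in encs]

    vocab = encs[0].vocab
    L = max(len(e) for e in encs)
    ids = np.full((len(encs), L), vocab.pad_id, dtype=np.int64)
    labs = np.full((len(encs), L), IGNORE, dtype=np.int64)
    attn = np.zeros((len(encs), L), dtype=np.int64)
    for i, (e, lab) in enumerate(zip(encs, region_labels)):
        ids[i, : len(e)] = e.token_ids
        labs[i, : len(lab)] = lab
        attn[i, : len(e)] = 1

    model = checkpoint.to_model()

    def train_step(take):
        sel = train_idx[take]
        out = model.forward(ids[sel], attn[sel])
        return loss_cls(out.region_logits, labs[sel], reduction="mean")

    def eval_on(idx_set):
        with ad.no_grad():
            out = model.forward(ids[idx_set], attn[idx_set])
        logits = out.region_logits.data
        preds, truth = [], []
        for row, i in enumerate(idx_set):
            counted = labs[i] != IGNORE
            preds.append(logits[row].argmax(axis=-1)[counted])
            truth.append(labs[i][counted])
        return evaluate(np.concatenate(preds), np.concatenate(truth),
                        seed=spec.seed)

    model, report, _ = _run_epochs(
        model, spec, len(train_idx), train_step,
        lambda: eval_on(val_idx), lambda: eval_on(test_idx),
    )
    return model, report


def finetune_replicates(
    checkpoint: Checkpoint,
    dataset,
    spec: FinetuneSpec,
    n_replicates: int = 3,
) -> tuple[list[EvalReport], float, float]:
    """Repeat fine-tuning with shifted seeds; returns (reports, mean, sd of F1)."""
    import dataclasses

    reports = []
    for r in range(n_replicates):
        s = dataclasses.replace(spec, seed=spec.seed + r)
        _, rep = finetune(checkpoint, dataset, s)
        reports.append(rep)
    f1s = [r.f1 for r in reports]
    return reports, float(np.mean(f1s)), float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0
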