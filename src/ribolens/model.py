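"""Encoder-only transformer for RNA with rotary position embedding.

The network is a BERT-style encoder: a token embedding (no absolute
position table — positions enter through rotary rotation of queries and
keys), ``layers`` pre-norm transformer blocks with multi-head self-attention
and a GELU feed-forward, a final layer norm, and four output heads:

* masked-nucleotide logits over the vocabulary (per position),
* secondary-structure logits over {'(', ')', '.'} (per position),
* genic-region logits over {5'UTR, CDS, 3'UTR} (per position),
* a sequence-level classification head reading the <cls> embedding.

Three pretraining objectives are implemented in their standard form: the
masked-nucleotide loss is the mean negative log-likelihood over masked
positions; the structure and region losses are cross-entropies summed over
counted positions (a per-position mean is also exposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .tokenizer import (
    DEFAULT_VOCAB,
    IGNORE,
    REGION_CLASSES,
    STRUCT_CLASSES,
    MaskingPlan,
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The full scale is 12 layers, 24 heads, embedding dimension 480
    (about 35M parameters with a 4x feed-forward); the defaults here are that
    scale, and every experiment in the test-suite uses a configured-down
    instance.
    """

    layers: int = 12
    heads: int = 24
    embed_dim: int = 480
    ffn_dim: Optional[int] = None  # default 4 * embed_dim
    context_len: int = 512
    vocab_size: int = len(DEFAULT_VOCAB)
    dropout: float = 0.0
    n_struct_classes: int = len(STRUCT_CLASSES)
    n_region_classes: int = len(REGION_CLASSES)
    n_seq_classes: int = 2
    rope_base: float = 10_000.0
    seq_pool: str = "mean"  # "mean" over unpadded tokens, or "cls"

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.context_len < 2:
            raise ValueError("context_len must be >= 2")

    @property
    def ffn(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.embed_dim

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads


@dataclass
class ModelOutput:
    token_embeddings: np.ndarray  # (B, L, D)
    mnm_logits: Tensor  # (B, L, vocab)
    ssp_logits: Tensor  # (B, L, |C|)
    region_logits: Tensor  # (B, L, |R|)
    seq_logits: Tensor  # (B, n_seq_classes)
    attentions: np.ndarray  # (layers, B, heads, L, L)
    attention_mask: np.ndarray  # (B, L)


class RNAEncoder:
    """The encoder network. Parameters live in a flat name -> Tensor dict.

    Computation runs in float32 by default (``dtype``); the standalone loss
    functions accept float64 inputs unchanged.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        def _init(*shape, scale: float = 0.02) -> Tensor:
            return Tensor(
                rng.normal(0.0, scale, size=shape).astype(dtype), requires_grad=True
            )

        def _ones(*shape) -> Tensor:
            return Tensor(np.ones(shape, dtype=dtype), requires_grad=True)

        def _zeros(*shape) -> Tensor:
            return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)

        c = config
        p: dict[str, Tensor] = {"embed": _init(c.vocab_size, c.embed_dim)}
        for l in range(c.layers):
            p[f"l{l}.wq"] = _init(c.embed_dim, c.embed_dim)
            p[f"l{l}.wk"] = _init(c.embed_dim, c.embed_dim)
            p[f"l{l}.wv"] = _init(c.embed_dim, c.embed_dim)
            p[f"l{l}.wo"] = _init(c.embed_dim, c.embed_dim)
            p[f"l{l}.ln1.g"] = _ones(c.embed_dim)
            p[f"l{l}.ln1.b"] = _zeros(c.embed_dim)
            p[f"l{l}.w1"] = _init(c.embed_dim, c.ffn)
            p[f"l{l}.b1"] = _zeros(c.ffn)
            p[f"l{l}.w2"] = _init(c.ffn, c.embed_dim)
            p[f"l{l}.b2"] = _zeros(c.embed_dim)
            p[f"l{l}.ln2.g"] = _ones(c.embed_dim)
            p[f"l{l}.ln2.b"] = _zeros(c.embed_dim)
        p["lnf.g"] = _ones(c.embed_dim)
        p["lnf.b"] = _zeros(c.embed_dim)
        for name, n_out in (
            ("mnm", c.vocab_size),
            ("ssp", c.n_struct_classes),
            ("region", c.n_region_classes),
            ("seq", c.n_seq_classes),
        ):
            p[f"head.{name}.w"] = _init(c.embed_dim, n_out)
            p[f"head.{name}.b"] = _zeros(n_out)
        self.params = p
        self._rope_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=self.dtype)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward -------------------------------------------------------------
    def _rope_tables(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        if length not in self._rope_cache:
            c = self.config
            h = c.head_dim // 2
            inv = c.rope_base ** (-np.arange(h) / h)
            ang = np.arange(length)[:, None] * inv[None, :]  # (L, h)
            self._rope_cache[length] = (
                np.cos(ang).astype(self.dtype),
                np.sin(ang).astype(self.dtype),
            )
        return self._rope_cache[length]

    def forward(
        self,
        token_ids: np.ndarray,
        attention_mask: Optional[np.ndarray] = None,
    ) -> ModelOutput:
        """Run the encoder on a (B, L) or (L,) id array.

        ``attention_mask`` is 1 at real tokens, 0 at padding; padded keys
        receive no attention mass. Raises on inputs longer than the context
        cap (truncate at the curation stage instead).
        """
        ids = np.atleast_2d(np.asarray(token_ids))
        B, L = ids.shape
        c = self.config
        if L > c.context_len:
            raise ValueError(
                f"input length {L} exceeds context cap {c.context_len}; "
                "truncate sequences during curation"
            )
        mask = (
            np.ones((B, L)) if attention_mask is None else np.atleast_2d(attention_mask)
        ).astype(self.dtype)
        addmask = (1.0 - mask)[:, None, None, :] * self.dtype(-1e9)  # on keys
        cos, sin = self._rope_tables(L)

        p = self.params
        x = ad.embedding(p["embed"], ids)  # (B, L, D)
        attns = np.empty((c.layers, B, c.heads, L, L), dtype=self.dtype)
        scale = 1.0 / np.sqrt(c.head_dim)

        for l in range(c.layers):
            h = ad.layer_norm(x, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])

            def split(t: Tensor) -> Tensor:  # (B,L,D) -> (B,H,L,hd)
                return t.reshape(B, L, c.heads, c.head_dim).transpose(0, 2, 1, 3)

            q = ad.rope(split(ad.linear(h, p[f"l{l}.wq"])), cos, sin)
            k = ad.rope(split(ad.linear(h, p[f"l{l}.wk"])), cos, sin)
            v = split(ad.linear(h, p[f"l{l}.wv"]))
            ctx, weights = ad.attention(q, k, v, addmask, scale)
            attns[l] = weights
            ctx = ctx.transpose(0, 2, 1, 3).reshape(B, L, c.embed_dim)
            x = x + ad.linear(ctx, p[f"l{l}.wo"])

            h2 = ad.layer_norm(x, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            ff = ad.linear(
                ad.gelu(ad.linear(h2, p[f"l{l}.w1"], p[f"l{l}.b1"])),
                p[f"l{l}.w2"],
                p[f"l{l}.b2"],
            )
            x = x + ff

        x = ad.layer_norm(x, p["lnf.g"], p["lnf.b"])

        def head(name: str, inp: Tensor) -> Tensor:
            return ad.linear(inp, p[f"head.{name}.w"], p[f"head.{name}.b"])

        if c.seq_pool == "cls":
            pooled = x[:, 0, :]  # (B, D)
        else:  # masked mean over real tokens; <cls> gets no pretraining
            w = mask / mask.sum(axis=1, keepdims=True)  # gradient, so pooling
            pooled = (x * Tensor(w[:, :, None])).sum(axis=1)  # is more stable
        return ModelOutput(
            token_embeddings=x.data,
            mnm_logits=head("mnm", x),
            ssp_logits=head("ssp", x),
            region_logits=head("region", x),
            seq_logits=head("seq", pooled),
            attentions=attns,
            attention_mask=mask,
        )

    __call__ = forward


# ---------------------------------------------------------------------------
# losses (the three pretraining objectives)
# ---------------------------------------------------------------------------


def _gather_logp(logits: Tensor, positions, targets, batch=None) -> Tensor:
    logp = logits.log_softmax(axis=-1)
    if logits.data.ndim == 3:
        b = np.zeros(len(positions), dtype=int) if batch is None else np.asarray(batch)
        return logp[b, np.asarray(positions), np.asarray(targets)]
    return logp[np.asarray(positions), np.asarray(targets)]


def loss_mnm(
    mnm_logits: Tensor, plan: MaskingPlan, batch: Optional[np.ndarray] = None
) -> Tensor:
    """Mean negative log-likelihood over the masked/corrupted positions."""
    if len(plan.selected) == 0:
        raise ValueError("masking plan selects no positions")
    lp = _gather_logp(mnm_logits, plan.selected, plan.targets, batch)
    return -lp.mean()


def _ce(logits: Tensor, labels: np.ndarray, reduction: str) -> Tensor:
    labels = np.asarray(labels)
    flat_logits = (
        logits.reshape(-1, logits.shape[-1]) if logits.data.ndim == 3 else logits
    )
    flat = labels.reshape(-1)
    counted = np.nonzero(flat != IGNORE)[0]
    if len(counted) == 0:
        raise ValueError("no counted positions (all labels are IGNORE)")
    lp = flat_logits.log_softmax(axis=-1)[counted, flat[counted]]
    total = -lp.sum()
    return total if reduction == "sum" else total * (1.0 / len(counted))


def loss_ssp(ssp_logits: Tensor, structure_labels, reduction: str = "sum") -> Tensor:
    """Secondary-structure cross-entropy; the canonical form is the sum,
    ``reduction='mean'`` divides by the number of counted positions."""
    return _ce(ssp_logits, structure_labels, reduction)


def loss_cls(region_logits: Tensor, region_labels, reduction: str = "sum") -> Tensor:
    """Genic-region cross-entropy (same form as the structure loss)."""
    return _ce(region_logits, region_labels, reduction)


def pretrain_step_loss(
    outputs: ModelOutput,
    plan: Optional[MaskingPlan],
    structure_labels=None,
    region_labels=None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    batch: Optional[np.ndarray] = None,
    reduction: str = "sum",
) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the active objectives; returns (loss, components)."""
    if not any(w != 0 for w in weights):
        raise ValueError("all objective weights are zero")
    terms: list[Tensor] = []
    comps: dict[str, float] = {}
    if weights[0] and plan is not None:
        t = loss_mnm(outputs.mnm_logits, plan, batch)
        comps["mnm"] = t.item()
        terms.append(weights[0] * t)
    if weights[1] and structure_labels is not None:
        t = loss_ssp(outputs.ssp_logits, structure_labels, reduction)
        comps["ssp"] = t.item()
        terms.append(weights[1] * t)
    if weights[2] and region_labels is not None:
        t = loss_cls(outputs.region_logits, region_labels, reduction)
        comps["cls"] = t.item()
        terms.append(weights[2] * t)
    if not terms:
        raise ValueError("no objective active (missing labels/plan)")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total, comps
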