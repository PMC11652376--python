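"""Single-nucleotide tokenization and the masked-nucleotide-modelling scheme.

Every nucleotide is one token; sequences are wrapped as
``<cls> b1 ... bN <eos>``. Per-token secondary-structure labels
('(' / ')' / '.') and genic-region labels (5'UTR / CDS / 3'UTR) ride along
with the token ids, with an ignore value at special-token positions.

The corruption scheme selects 20% of nucleotides per sequence (default);
of the selected, half become ``<mask>``, a quarter are replaced by a
uniformly random base, and a quarter are left unchanged — i.e. 10% / 5% / 5%
of the sequence. Counts are made exact per sequence by largest-remainder
apportionment, so the scheme is deterministic in its proportions and
reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import GenicRegions, normalize_rna

log = logging.getLogger(__name__)

IGNORE = -100  # label value excluded from every loss

BASES = ("A", "C", "G", "U")
SPECIALS = ("<cls>", "<pad>", "<eos>", "<unk>", "<mask>")

STRUCT_CLASSES = ("(", ")", ".")
REGION_CLASSES = ("utr5", "cds", "utr3")

MASK_ACTION, RANDOM_ACTION, KEEP_ACTION = "mask_token", "random_base", "keep"


@dataclass(frozen=True)
class Vocabulary:
    """Token vocabulary: 4 bases, 5 special tokens, inert placeholders.

    Ids are dense from 0. Placeholder tokens reserve space for chemically
    modified bases in future corpora; they are never emitted by the encoder.
    """

    n_placeholders: int = 8
    tokens: tuple[str, ...] = field(init=False)
    token_to_id: dict = field(init=False)

    def __post_init__(self) -> None:
        toks = SPECIALS + BASES + tuple(
            f"<ph{i}>" for i in range(self.n_placeholders)
        )
        object.__setattr__(self, "tokens", toks)
        object.__setattr__(self, "token_to_id", {t: i for i, t in enumerate(toks)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def cls_id(self) -> int:
        return self.token_to_id["<cls>"]

    @property
    def pad_id(self) -> int:
        return self.token_to_id["<pad>"]

    @property
    def eos_id(self) -> int:
        return self.token_to_id["<eos>"]

    @property
    def unk_id(self) -> int:
        return self.token_to_id["<unk>"]

    @property
    def mask_id(self) -> int:
        return self.token_to_id["<mask>"]

    @property
    def base_ids(self) -> tuple[int, ...]:
        return tuple(self.token_to_id[b] for b in BASES)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.token_to_id, indent=1))


DEFAULT_VOCAB = Vocabulary()


@dataclass
class EncodedSequence:
    """Token ids plus aligned per-token labels and an attention mask."""

    token_ids: np.ndarray
    structure_labels: np.ndarray
    region_labels: np.ndarray
    attention_mask: np.ndarray
    vocab: Vocabulary = field(default=DEFAULT_VOCAB, repr=False)

    def __post_init__(self) -> None:
        n = len(self.token_ids)
        for v in (self.structure_labels, self.region_labels, self.attention_mask):
            if len(v) != n:
                raise ValueError("all encoded vectors must share one length")

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def base_positions(self) -> np.ndarray:
        """Positions holding (possibly unknown) nucleotide tokens."""
        ids = self.token_ids
        special = np.isin(
            ids, [self.vocab.cls_id, self.vocab.eos_id, self.vocab.pad_id]
        )
        return np.nonzero(~special)[0]


def encode_structure_labels(
    dotbracket: str, validate: bool = True
) -> np.ndarray:
    """Map a dot-bracket string to the 3-class label vector."""
    if validate:
        depth = 0
        for ch in dotbracket:
            if ch not in STRUCT_CLASSES:
                raise ValueError(f"foreign character {ch!r} in dot-bracket")
            depth += 1 if ch == "(" else (-1 if ch == ")" else 0)
            if depth < 0:
                raise ValueError("unbalanced dot-bracket")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket")
    lut = {c: i for i, c in enumerate(STRUCT_CLASSES)}
    return np.array([lut[c] for c in dotbracket], dtype=np.int64)


def encode_region_labels(regions: GenicRegions, length: int) -> np.ndarray:
    """Per-base region class vector; intervals must tile [0, length)."""
    regions.validate(length)
    out = np.empty(length, dtype=np.int64)
    for cls, (lo, hi) in enumerate((regions.utr5, regions.cds, regions.utr3)):
        out[lo:hi] = cls
    return out


def encode(
    sequence: str,
    structure: Optional[str] = None,
    regions: Optional[GenicRegions] = None,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> EncodedSequence:
    """Tokenize one sequence with optional aligned annotations.

    Output layout is ``<cls> b1..bN <eos>``; unknown characters map to
    ``<unk>``; labels are shifted to align with the body and set to IGNORE at
    the flanking special tokens.
    """
    seq = normalize_rna(sequence)
    n = len(seq)
    if structure is not None and len(structure) != n:
        raise ValueError("structure length != sequence length")
    ids = np.empty(n + 2, dtype=np.int64)
    ids[0], ids[-1] = vocab.cls_id, vocab.eos_id
    for i, ch in enumerate(seq):
        ids[i + 1] = vocab.token_to_id.get(ch, vocab.unk_id)

    struct = np.full(n + 2, IGNORE, dtype=np.int64)
    if structure is not None:
        struct[1 : n + 1] = encode_structure_labels(structure)
    region = np.full(n + 2, IGNORE, dtype=np.int64)
    if regions is not None:
        region[1 : n + 1] = encode_region_labels(regions, n)
    return EncodedSequence(
        ids, struct, region, np.ones(n + 2, dtype=np.int64), vocab
    )


def decode(encoded: EncodedSequence) -> str:
    """Inverse of :func:`encode` for the sequence body."""
    vocab = encoded.vocab
    id_to_tok = vocab.tokens
    out = []
    for i in encoded.base_positions:
        tok = id_to_tok[encoded.token_ids[i]]
        out.append(tok if len(tok) == 1 else "N")
    return "".join(out)


@dataclass
class MaskingPlan:
    """Record of one corruption draw: where, what, and the originals."""

    selected: np.ndarray
    actions: dict  # position -> action string
    targets: np.ndarray  # original token ids at `selected`
    seed: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion n into integer parts proportional to `fractions` exactly."""
    raw = [n * f for f in fractions]
    base = [int(math.floor(r)) for r in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def apply_mnm_mask(
    encoded: EncodedSequence, rate: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, MaskingPlan]:
    """Corrupt a tokenized sequence for masked-nucleotide modelling.

    Selects ``round(rate * eligible)`` base positions; of those, 1/2 get the
    ``<mask>`` token, 1/4 a uniformly random base (possibly the original) and
    1/4 are kept as-is, with exact per-sequence counts via largest-remainder.
    Returns the corrupted id vector and the plan (the original ids at the
    selected positions are the prediction targets).
    """
    if not (0 < rate < 1):
        raise ValueError("rate must be in (0, 1)")
    vocab = encoded.vocab
    eligible = np.nonzero(np.isin(encoded.token_ids, vocab.base_ids))[0]
    n_elig = len(eligible)
    if n_elig == 0:
        raise ValueError("sequence has no eligible base positions")
    n_sel = _round_half_away(rate * n_elig)
    if n_elig < 5:
        n_sel = max(1, n_sel)
        log.warning("only %d eligible positions; selecting %d", n_elig, n_sel)
    n_sel = max(1, n_sel)

    rng = np.random.default_rng(seed)
    selected = np.sort(rng.choice(eligible, size=n_sel, replace=False))
    n_mask, n_rand, n_keep = _largest_remainder(n_sel, (0.5, 0.25, 0.25))
    perm = rng.permutation(n_sel)

    corrupted = encoded.token_ids.copy()
    targets = encoded.token_ids[selected].copy()
    actions: dict[int, str] = {}
    base_ids = np.array(vocab.base_ids)
    for rank, idx in enumerate(perm):
        pos = int(selected[idx])
        if rank < n_mask:
            corrupted[pos] = vocab.mask_id
            actions[pos] = MASK_ACTION
        elif rank < n_mask + n_rand:
            corrupted[pos] = int(base_ids[rng.integers(4)])
            actions[pos] = RANDOM_ACTION
        else:
            actions[pos] = KEEP_ACTION
    return corrupted, MaskingPlan(selected, actions, targets, seed)
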