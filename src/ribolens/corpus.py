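"""Transcript corpus curation and translation-efficiency labelling.

This module ingests transcript sequences (FASTA) with genic-region
annotations (5'UTR / CDS / 3'UTR), applies the curation rules used to build
the pretraining corpus — length truncation and filtering, redundancy removal
at a sequence-identity cut-off, and local secondary-structure annotation —
and derives binary translation-efficiency (TE) labels from polysome and
RNA-seq count tables.

Coordinates are 0-based half-open internally; on-disk region tables are
1-based inclusive (converted on read/write).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick plus G.U wobble pairs, the pairing rule used throughout.
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert DNA-style T to U. Does not validate."""
    return sequence.upper().replace("T", "U")


def is_valid_rna(sequence: str) -> bool:
    return set(sequence) <= RNA_ALPHABET


@dataclass(frozen=True)
class GenicRegions:
    """Half-open intervals (utr5, cds, utr3) tiling [0, length)."""

    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def validate(self, length: int) -> None:
        u5, cd, u3 = self.utr5, self.cds, self.utr3
        if not (u5[0] == 0 and u5[1] == cd[0] and cd[1] == u3[0] and u3[1] == length):
            raise ValueError(
                f"regions {u5},{cd},{u3} do not tile [0,{length}) in order "
                "utr5->cds->utr3"
            )
        for lo, hi in (u5, cd, u3):
            if lo > hi:
                raise ValueError(f"negative-length interval ({lo},{hi})")

    def clipped(self, length: int) -> "GenicRegions":
        """Clip all intervals to [0, length) (used after 3' truncation)."""

        def clip(iv: tuple[int, int]) -> tuple[int, int]:
            return (min(iv[0], length), min(iv[1], length))

        return GenicRegions(clip(self.utr5), clip(self.cds), clip(self.utr3))


@dataclass
class TranscriptRecord:
    """A transcript: RNA sequence, optional genic regions, optional structure.

    ``structure`` is a Vienna dot-bracket string of the same length as
    ``sequence`` once local structure has been annotated.
    """

    id: str
    sequence: str
    regions: Optional[GenicRegions] = None
    structure: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if self.regions is not None:
            self.regions.validate(len(self.sequence))
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError("structure length must equal sequence length")

    @property
    def utr5(self) -> str:
        if self.regions is None:
            raise ValueError(f"{self.id}: no region annotation")
        lo, hi = self.regions.utr5
        return self.sequence[lo:hi]


@dataclass(frozen=True)
class CurationConfig:
    """Corpus curation thresholds.

    Defaults: truncate above 1,026 nt, drop
    below 20 nt, remove redundancy at 80% identity, annotate local structure
    with a 30-nt maximum base-pair span.
    """

    max_len: int = 1026
    min_len: int = 20
    identity_threshold: float = 0.8
    max_bp_span: int = 30
    require_annotation: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len < self.max_len):
            raise ValueError("need 0 < min_len < max_len")
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.max_bp_span < 3:
            raise ValueError("max_bp_span must be >= 3")


# ---------------------------------------------------------------------------
# identity clustering (greedy, CD-HIT style)
# ---------------------------------------------------------------------------


def _pair_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Best ungapped containment identity of the shorter in the longer.

    The shorter sequence is slid along the longer at every full-containment
    offset; identity is the maximal match count divided by the shorter
    length.
    """
    if len(a) > len(b):
        a, b = b, a
    ls = len(a)
    if ls == 0:
        return 0.0
    windows = np.lib.stride_tricks.sliding_window_view(b, ls)
    matches = (windows == a).sum(axis=1)
    return int(matches.max()) / ls


def identity_cluster(
    sequences: Sequence[str], threshold: float = 0.8
) -> list[int]:
    """Greedy longest-first redundancy clustering; returns representative indices.

    Mirrors the cd-hit-est strategy at small scale: sequences are visited in
    decreasing length order (ties broken by input order); each joins the first
    existing representative with ungapped best-window identity >= ``threshold``
    or founds a new cluster. Deterministic given input order. Returned indices
    are sorted, so the representative set is order-stable with the input.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    arrays = [
        np.frombuffer(sequences[i].encode("ascii"), dtype=np.uint8)
        for i in range(len(sequences))
    ]
    reps: list[int] = []
    for i in order:
        if not any(_pair_identity(arrays[i], arrays[r]) >= threshold for r in reps):
            reps.append(i)
    return sorted(reps)


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------


def curate(
    records: Iterable[TranscriptRecord],
    config: CurationConfig = CurationConfig(),
    annotate_structure: bool = False,
) -> list[TranscriptRecord]:
    """Apply the full curation protocol to a transcript set.

    Steps, in order: reject records with non-ACGU(T) characters (warning, not
    an error); drop records lacking region annotation when
    ``config.require_annotation``; truncate sequences above ``max_len`` to
    exactly ``max_len`` keeping the 5' end; drop sequences below ``min_len``;
    remove redundancy at ``identity_threshold`` with :func:`identity_cluster`;
    optionally annotate local structure. Output order follows input order.
    """
    from .folding import annotate_local_structure

    kept: list[TranscriptRecord] = []
    for rec in records:
        seq = normalize_rna(rec.sequence)
        if not is_valid_rna(seq):
            bad = sorted(set(seq) - RNA_ALPHABET)
            log.warning("rejecting %s: non-ACGU characters %s", rec.id, bad)
            continue
        if config.require_annotation and rec.regions is None:
            log.warning("rejecting %s: missing region annotation", rec.id)
            continue
        if len(seq) > config.max_len:
            regions = (
                rec.regions.clipped(config.max_len) if rec.regions else None
            )
            rec = TranscriptRecord(rec.id, seq[: config.max_len], regions)
        if len(rec.sequence) < config.min_len:
            continue
        kept.append(rec)

    reps = identity_cluster(
        [r.sequence for r in kept], config.identity_threshold
    )
    out = [kept[i] for i in reps]
    if annotate_structure:
        out = [
            replace(
                r, structure=annotate_local_structure(r.sequence, config.max_bp_span)
            )
            for r in out
        ]
    return out


# ---------------------------------------------------------------------------
# TE labelling
# ---------------------------------------------------------------------------

LABEL_HIGH = 1
LABEL_LOW = 0


@dataclass
class TEEntry:
    id: str
    te: float
    label: Optional[int]  # 1 high, 0 low, None unlabelled
    utr5: Optional[str] = None


@dataclass
class TEDataset:
    """Per-gene TE values with mean +/- sd binary labels.

    ``label`` is 1 (high) when te >= mean + sd, 0 (low) when te <= mean - sd,
    and None otherwise.
    """

    entries: list[TEEntry]
    mean: float
    sd: float

    @property
    def labelled(self) -> list[TEEntry]:
        return [e for e in self.entries if e.label is not None]

    def attach_sequences(self, utr5_by_id: dict[str, str]) -> "TEDataset":
        for e in self.entries:
            if e.id in utr5_by_id:
                e.utr5 = normalize_rna(utr5_by_id[e.id])
        return self


def rpkm(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Reads per kilobase per million mapped reads.

    counts * 1e9 / (library_size * length); library size is the column total.
    """
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("library has zero total counts")
    return counts * 1e9 / (total * lengths)


def compute_te_labels(
    polysome_counts: pd.Series,
    rnaseq_counts: pd.Series,
    lengths: pd.Series,
    min_rpkm: float = 1.0,
) -> TEDataset:
    """Derive TE values and high/low labels from count tables.

    RPKM is computed per library; genes below ``min_rpkm`` in either library
    are removed; TE = polysome RPKM / RNA-seq RPKM; labels are assigned by
    the mean +/- sd rule (sample sd, ddof=1).
    """
    common = polysome_counts.index.intersection(rnaseq_counts.index).intersection(
        lengths.index
    )
    if len(common) < len(polysome_counts) or len(common) < len(rnaseq_counts):
        log.warning(
            "gene sets differ between tables; intersecting to %d genes", len(common)
        )
    poly = rpkm(polysome_counts.loc[common].astype(float), lengths.loc[common])
    rna = rpkm(rnaseq_counts.loc[common].astype(float), lengths.loc[common])
    ok = (poly >= min_rpkm) & (rna >= min_rpkm)
    te = (poly[ok] / rna[ok]).astype(float)

    mean = float(te.mean()) if len(te) else float("nan")
    sd = float(te.std(ddof=1)) if len(te) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("degenerate TE distribution (sd = 0); no gene labelled")

    entries = []
    for gid, val in te.items():
        if sd > 0 and val >= mean + sd:
            lab: Optional[int] = LABEL_HIGH
        elif sd > 0 and val <= mean - sd:
            lab = LABEL_LOW
        else:
            lab = None
        entries.append(TEEntry(str(gid), float(val), lab))
    return TEDataset(entries, mean, sd)
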