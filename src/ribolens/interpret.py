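"""Attention-contrast interpretability.

Attention maps are taken from two fine-tuned models — the true model
(trained on real TE labels) and a background model (same data, permuted
labels) — reduced by averaging over layers and heads, subtracted
(true - background) and clamped at zero. The per-position score is the mean
attention a position *receives* (column mean of the clamped matrix). Scores
are standardized across the whole cohort and positions above a
standard-normal quantile are called as high-attention sites; both the
two-sided-1% (2.576) and one-sided-1% (2.326) thresholds are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats


def z_threshold(alpha_mode: Literal["one_sided_1pct", "two_sided_1pct"]) -> float:
    """Standard-normal quantile for the chosen calling mode."""
    if alpha_mode == "two_sided_1pct":
        return float(stats.norm.ppf(1 - 0.01 / 2))
    if alpha_mode == "one_sided_1pct":
        return float(stats.norm.ppf(1 - 0.01))
    raise ValueError(f"unknown alpha_mode {alpha_mode!r}")


def reduce_attention(raw: np.ndarray, n_real: Optional[int] = None) -> np.ndarray:
    """Average a (layers, heads, L, L) — or (layers, B=1, heads, L, L) —
    attention stack to a single L x L matrix.

    ``n_real`` restricts to the first n unpadded positions.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 5:
        if arr.shape[1] != 1:
            raise ValueError("pass one sequence at a time")
        arr = arr[:, 0]
    if arr.ndim != 4:
        raise ValueError("expected (layers, heads, L, L) attention stack")
    if arr.size == 0:
        raise ValueError("empty attention stack")
    red = arr.mean(axis=(0, 1))
    if n_real is not None:
        red = red[:n_real, :n_real]
    return red


@dataclass
class AttentionContrast:
    """Nonnegative contrast matrix and derived per-position scores."""

    matrix: np.ndarray
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)


def contrast(
    true_reduced: np.ndarray,
    background_reduced: np.ndarray,
    provenance: Optional[dict] = None,
) -> AttentionContrast:
    """Subtract background attention from true attention and clamp at zero.

    The per-position score of position i is the column mean of the clamped
    matrix — the average contrast attention i receives from all positions.
    """
    t = np.asarray(true_reduced, dtype=np.float64)
    b = np.asarray(background_reduced, dtype=np.float64)
    if t.shape != b.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {b.shape}")
    mat = np.clip(t - b, 0.0, None)
    scores = mat.mean(axis=0)
    prov = {"direction": "true_minus_background", "reduction": "mean_layers_heads",
            "score": "column_mean_after_clamp"}
    prov.update(provenance or {})
    return AttentionContrast(mat, scores, prov)


@dataclass
class HighAttentionCalls:
    z: list[np.ndarray]
    threshold: float
    called: list[np.ndarray]
    tail: str
    mean: float
    sd: float

    @property
    def called_fraction(self) -> float:
        n = sum(len(z) for z in self.z)
        return sum(len(c) for c in self.called) / n if n else 0.0


def call_high_attention(
    cohort_scores: Sequence[np.ndarray],
    alpha_mode: Literal["one_sided_1pct", "two_sided_1pct"] = "two_sided_1pct",
) -> HighAttentionCalls:
    """Standardize scores across the cohort and call z > threshold.

    The mean and standard deviation are pooled over every position of every
    sequence in the cohort (not per sequence).
    """
    seqs = [np.asarray(s, dtype=np.float64) for s in cohort_scores]
    flat = np.concatenate(seqs) if seqs else np.empty(0)
    if flat.size < 2:
        raise ValueError("need at least two positions to standardize")
    mean, sd = float(flat.mean()), float(flat.std(ddof=1))
    if sd == 0.0:
        raise ValueError("constant scores: z undefined (sd = 0)")
    thr = z_threshold(alpha_mode)
    zs = [(s - mean) / sd for s in seqs]
    called = [np.nonzero(z > thr)[0] for z in zs]
    return HighAttentionCalls(zs, thr, called, alpha_mode, mean, sd)


def positional_metaprofile(
    scores_with_aug: Sequence[tuple[np.ndarray, int]],
    window: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average per-position scores in coordinates anchored at the AUG.

    Each item is (per-position scores along the transcript/5'UTR, index of
    the first AUG base in those coordinates). Offset -1 is the base
    immediately upstream of the AUG. Sequences shorter than the window
    contribute the offsets they have. Returns (offsets, mean_scores, n).
    """
    if not scores_with_aug:
        raise ValueError("no sequences with a known AUG position")
    offsets = np.arange(-window, 0)
    total = np.zeros(window)
    count = np.zeros(window, dtype=int)
    for scores, aug in scores_with_aug:
        scores = np.asarray(scores, dtype=np.float64)
        for k, off in enumerate(offsets):
            pos = aug + off
            if 0 <= pos < len(scores):
                total[k] += scores[pos]
                count[k] += 1
    if not count.any():
        raise ValueError("no sequence contributes any upstream offset")
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return offsets, mean, count


def logo_information_content(
    aligned: Sequence[str], alphabet: str = "ACGU"
) -> np.ndarray:
    """Per-position information content (bits) of an equal-length alignment.

    IC_p = 2 - H_p with H_p the Shannon entropy of the base frequencies at
    position p; ranges from 0 (uniform usage) to 2 (perfectly conserved).
    """
    if not aligned:
        raise ValueError("empty alignment")
    L = len(aligned[0])
    if any(len(s) != L for s in aligned):
        raise ValueError("alignment windows must be equal length")
    counts = np.zeros((L, len(alphabet)))
    index = {b: i for i, b in enumerate(alphabet)}
    for s in aligned:
        for p, ch in enumerate(s):
            if ch in index:
                counts[p, index[ch]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(totals > 0, counts / totals, 0.0)
        h = np.where(f > 0, -f * np.log2(f), 0.0).sum(axis=1)
    return 2.0 - h
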