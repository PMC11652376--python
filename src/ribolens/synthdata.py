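"""Synthetic transcriptomes with planted, causally labelled RNA motifs.

The generator emulates the study design end to end without any external
corpus: random transcripts with a 5'UTR / AUG-anchored CDS / 3'UTR
architecture; motif plants in the 5'UTR (a Kozak-like sequence context just
upstream of the AUG, a GC-stem hairpin, a mixed GC/AU-stem hairpin, and a
GGA-repeat rG4); binary translation-efficiency labels drawn through a
logistic link on the summed plant effects (plus optional flip noise); and
negative-binomial polysome / RNA-seq count tables whose ratio reflects the
TE class, for exercising the RPKM-filtered labelling path.

Every insertion is recorded in a plant ledger so recovery tests can compare
discovered motifs against ground truth. All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import GenicRegions, TranscriptRecord

SIGMOID = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731

#: canonical planted motifs (stems pair under Watson-Crick rules)
KOZAK_LIKE = "ACAACCAACA"  # context spanning offsets -10..-1 from the AUG
GC_STEM_HAIRPIN = "GCGC" + "AAAA" + "GCGC"  # 4 GC pairs in the stem
MIXED_STEM_HAIRPIN = "ACGU" + "AAAA" + "ACGU"  # 2 AU + 2 GC pairs
RG4_GGA = "GGAGGAGGAGG"  # 4 tracts of GG separated by single-A loops


@dataclass(frozen=True)
class PlantSpec:
    """One planted motif class.

    ``effect`` is the log-odds shift on P(high TE) carried by the plant;
    ``prevalence`` the fraction of transcripts assigned to this class
    (classes are mutually exclusive per transcript); ``offset_range`` is
    used by ``anchor='aug'`` plants and gives the allowed offsets of the
    motif's last base relative to the AUG (e.g. -1 places it immediately
    upstream); ``mutation_rate`` mutates planted bases uniformly to model
    motif degeneracy.
    """

    name: str
    kind: Literal["sequence", "hairpin", "rg4"]
    motif: str
    effect: float
    prevalence: float
    anchor: Literal["aug", "uniform"] = "uniform"
    offset_range: tuple[int, int] = (-1, -1)
    mutation_rate: float = 0.0
    #: flank the insertion with single A boundaries so the planted motif is
    #: maximal (random flanks cannot extend a stem or a G-tract)
    cap: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.prevalence <= 1):
            raise ValueError("prevalence must be in [0, 1]")


def standard_plants(mutation_rate: float = 0.0) -> list[PlantSpec]:
    """The four motif classes emulated by the recovery study.

    High-TE: Kozak-like context at the AUG (+6 log-odds), mixed-stem
    hairpin (+6). Low-TE: GC-stem hairpin and GGA-repeat rG4 with strongly
    repressive effects (-20), so they act as vetoes: a repressive structure
    keeps the transcript low-TE even when a promoting motif is present.
    The veto design makes every class causally pivotal — a classifier
    cannot reach high accuracy by detecting the promoting motifs alone, so
    it must also learn the repressive ones, which is exactly the linkage
    the attention-contrast analysis is meant to expose.

    The AUG-anchored context is drawn independently per transcript; the
    structural classes are mutually exclusive (a 5'UTR this short holds one
    structural motif), with the remainder left unstructured. Transcripts
    with no motif at all get a fair-coin label through the logistic link.
    """
    return [
        # the context is a composition bias, not an invariant string: each
        # planted copy is drawn PWM-like around the consensus (30% per-base
        # divergence), as a real initiation context would be
        PlantSpec("kozak", "sequence", KOZAK_LIKE, +6.0, 0.40,
                  anchor="aug", offset_range=(-1, -1),
                  mutation_rate=0.3),
        PlantSpec("gc_stem", "hairpin", GC_STEM_HAIRPIN, -20.0, 0.30,
                  mutation_rate=mutation_rate),
        PlantSpec("mixed_stem", "hairpin", MIXED_STEM_HAIRPIN, +6.0, 0.30,
                  mutation_rate=mutation_rate),
        PlantSpec("rg4", "rg4", RG4_GGA, -20.0, 0.26,
                  mutation_rate=mutation_rate),
    ]


@dataclass(frozen=True)
class SynthConfig:
    """Scale and noise of the synthetic transcriptome.

    Defaults are the desk-scale study conditions: 400 transcripts with
    30-48 nt 5'UTRs (long enough to host any plant with flanks), uniform
    base composition, 2% label-flip noise, and mild count overdispersion.
    """

    n_transcripts: int = 400
    utr5_len: tuple[int, int] = (30, 48)
    cds_len: tuple[int, int] = (24, 42)
    utr3_len: tuple[int, int] = (6, 12)
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    label_flip: float = 0.02
    dispersion: float = 0.05
    base_logit: float = 0.0
    aug_margin: int = 9  # hairpin/rG4 plants stay this far from the AUG
    #: effect-free decoys make composition alone non-discriminative, so the
    #: classifier must recognize motif arrangement/position: sub-threshold
    #: G-tract fragments, and Kozak-like copies away from the AUG
    decoy_gtract_rate: float = 0.5
    decoy_kozak_rate: float = 0.3


@dataclass
class PlantLedger:
    """Ground truth of every insertion (and skipped insertions)."""

    entries: list[dict] = field(default_factory=list)

    def for_class(self, name: str) -> list[dict]:
        return [e for e in self.entries if e["plant"] == name and not e.get("skipped")]


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(list("ACGU"), size=length, p=list(probs)))


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    if rate <= 0:
        return motif
    out = list(motif)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGU"[rng.integers(4)]
    return "".join(out)


def generate_transcriptome(
    config: SynthConfig,
    plants: Optional[Sequence[PlantSpec]] = None,
) -> tuple[list[TranscriptRecord], dict[str, int], PlantLedger]:
    """Generate transcripts, binary TE labels and the plant ledger.

    AUG-anchored plants are drawn independently per transcript (each with
    its own prevalence); structural (uniform-placement) plants are mutually
    exclusive — one categorical draw over their prevalences, with the
    remainder carrying no structural motif. Plant effects add on the
    log-odds scale and the label is Bernoulli(sigmoid(base_logit + sum)),
    then flipped with probability ``label_flip``. Plants that do not fit
    their target UTR are skipped with a ledger note.
    """
    plants = list(plants) if plants is not None else []
    anchored = [p for p in plants if p.anchor == "aug"]
    structural = [p for p in plants if p.anchor != "aug"]
    s_prev = sum(p.prevalence for p in structural)
    if s_prev > 1.0 + 1e-9:
        raise ValueError("structural plant prevalences exceed 1")
    s_probs = [p.prevalence for p in structural] + [1.0 - s_prev]
    rng = np.random.default_rng(config.seed)

    records: list[TranscriptRecord] = []
    labels: dict[str, int] = {}
    ledger = PlantLedger()
    for i in range(config.n_transcripts):
        tid = f"synth{i:05d}"
        u5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        cds = int(rng.integers(config.cds_len[0], config.cds_len[1] + 1))
        u3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        utr5 = list(_random_seq(rng, u5, config.base_probs))
        body = "AUG" + _random_seq(rng, cds - 3, config.base_probs)
        utr3 = _random_seq(rng, u3, config.base_probs)

        effect = config.base_logit
        occupied: list[tuple[int, int]] = []
        carried: set[str] = set()

        def insert(spec: PlantSpec) -> None:
            nonlocal effect
            motif = _mutate(rng, spec.motif, spec.mutation_rate)
            lcap = "A" if spec.cap else ""
            rcap = "A" if (spec.cap and spec.anchor != "aug") else ""
            ins = lcap + motif + rcap
            if spec.anchor == "aug":
                off = int(rng.integers(spec.offset_range[0],
                                       spec.offset_range[1] + 1))
                start = u5 + off + 1 - len(ins)
                if any(start < e and b < start + len(ins)
                       for b, e in occupied):
                    start = -1
            else:
                hi = u5 - len(ins) - config.aug_margin
                start = _try_place(rng, len(ins), hi, occupied)
            if start < 0:
                ledger.entries.append(
                    {"transcript": tid, "plant": spec.name, "skipped": True}
                )
                return
            utr5[start : start + len(ins)] = list(ins)
            occupied.append((start, start + len(ins)))
            effect += spec.effect
            carried.add(spec.name)
            ledger.entries.append(
                {
                    "transcript": tid,
                    "plant": spec.name,
                    "start": start + len(lcap),
                    "end": start + len(lcap) + len(motif),
                    "motif": motif,
                }
            )

        choice = int(rng.choice(len(s_probs), p=s_probs))
        if choice < len(structural):
            insert(structural[choice])
        for spec in anchored:
            if rng.random() < spec.prevalence:
                insert(spec)

        # effect-free decoys (see SynthConfig)
        if "rg4" not in carried and rng.random() < config.decoy_gtract_rate:
            ins = "AGGAGGA"  # two G-tracts: below the rG4 threshold
            s = _try_place(rng, len(ins), u5 - len(ins) - config.aug_margin,
                           occupied)
            if s >= 0:
                utr5[s : s + len(ins)] = list(ins)
                occupied.append((s, s + len(ins)))
        if "kozak" not in carried and rng.random() < config.decoy_kozak_rate:
            ins = KOZAK_LIKE  # right motif, wrong position: no effect
            s = _try_place(rng, len(ins), u5 - len(ins) - config.aug_margin,
                           occupied)
            if s >= 0:
                utr5[s : s + len(ins)] = list(ins)
                occupied.append((s, s + len(ins)))

        utr5 = "".join(utr5)
        seq = utr5 + body + utr3
        label = int(rng.random() < SIGMOID(effect))
        if rng.random() < config.label_flip:
            label = 1 - label
        regions = GenicRegions((0, u5), (u5, u5 + cds), (u5 + cds, len(seq)))
        records.append(TranscriptRecord(tid, seq, regions))
        labels[tid] = label
    return records, labels, ledger


def _try_place(rng, width: int, hi: int, occupied) -> int:
    """A start in [1, hi) whose span avoids occupied regions, or -1."""
    if hi <= 1:
        return -1
    for _ in range(10):
        s = int(rng.integers(1, hi))
        if all(s >= e + 1 or s + width <= b - 1 for b, e in occupied):
            return s
    return -1


def generate_count_tables(
    labels: dict[str, int],
    lengths: dict[str, int],
    config: SynthConfig,
    te_high: float = 4.0,
    te_low: float = 0.25,
    mean_expression: float = 200.0,
    low_expression_fraction: float = 0.05,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Negative-binomial polysome / RNA-seq counts reflecting TE classes.

    Genes labelled high get a polysome/RNA ratio of ``te_high`` (low:
    ``te_low``; unlabelled entries, passed as label None, get 1.0), each
    jittered by the configured dispersion. A ``low_expression_fraction`` of
    genes is given near-zero expression so the RPKM >= 1 filter has work to
    do. Returns (polysome counts, rnaseq counts, lengths) as Series.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = list(labels)
    n = len(ids)
    te = np.array(
        [te_high if labels[g] == 1 else te_low if labels[g] == 0 else 1.0
         for g in ids]
    )
    te = te * rng.lognormal(0.0, config.dispersion, size=n)
    base = rng.lognormal(np.log(mean_expression), 0.4, size=n)
    lowmask = rng.random(n) < low_expression_fraction
    base[lowmask] *= 1e-4

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.dispersion <= 1e-9:
            return rng.poisson(mean).astype(float)
        r = 1.0 / config.dispersion
        return rng.negative_binomial(r, r / (r + mean)).astype(float)

    rna = draw(base)
    poly = draw(base * te)
    lens = pd.Series({g: lengths[g] for g in ids}, dtype=float)
    return (
        pd.Series(poly, index=ids),
        pd.Series(rna, index=ids),
        lens,
    )
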