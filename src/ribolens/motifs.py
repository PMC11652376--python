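"""Structure-motif and rG4 discovery from attention contrast.

The discovery chain:

1. a seed library of hairpin motifs is enumerated from 5'UTRs (stems 4-7 bp,
   loops 4-9 nt, total length <= 30, Watson-Crick + G.U pairing);
2. each seed with >= 3 occurrences is tested by a paired t-test of mean
   contrast score inside the occurrence footprint against the rest of the
   same 5'UTR, and p-values are Benjamini-Hochberg corrected;
3. significant seeds (q < 0.01) are one-hot encoded (with a paired-position
   channel), Ward-clustered at every cut k in 2..100, and clusters with at
   least 30 members are tested for TE direction by two-sided Fisher's exact
   test on host-transcript labels;
4. clusters with Fisher p < 0.05 and average positional information content
   (APIC) >= 1.5 bits are reported with their odds-ratio direction;
5. rG4 candidates (>= 4 G-tracts of >= 2 Gs, loops 1-7 nt) are scanned
   directly from the sequence, scored with the same paired design, and
   BH-corrected within each rG4 length stratum.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .corpus import CANONICAL_PAIRS, TranscriptRecord
from .interpret import logo_information_content

log = logging.getLogger(__name__)

STEM_RANGE = (4, 7)
LOOP_RANGE = (4, 9)
MAX_SEED_LEN = 30
MIN_OCCURRENCES = 3
MIN_CLUSTER_MEMBERS = 30
SEED_Q_THRESHOLD = 0.01
FISHER_P_THRESHOLD = 0.05
APIC_THRESHOLD = 1.5


@dataclass(frozen=True)
class StructureSeed:
    """One hairpin occurrence: sequence, structure, geometry, and source."""

    sequence: str
    dotbracket: str
    stem_len: int
    loop_len: int
    source: tuple[str, int, int]  # transcript id, start, end (half-open)

    def __post_init__(self) -> None:
        if not (STEM_RANGE[0] <= self.stem_len <= STEM_RANGE[1]):
            raise ValueError(f"stem length {self.stem_len} outside {STEM_RANGE}")
        if not (LOOP_RANGE[0] <= self.loop_len <= LOOP_RANGE[1]):
            raise ValueError(f"loop length {self.loop_len} outside {LOOP_RANGE}")
        if len(self.sequence) > MAX_SEED_LEN:
            raise ValueError("seed exceeds maximum length")

    @property
    def motif_key(self) -> tuple[str, str]:
        return (self.sequence, self.dotbracket)


def _pairable(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def enumerate_hairpins(
    sequence: str,
    transcript_id: str = "",
    offset: int = 0,
    stem_range: tuple[int, int] = STEM_RANGE,
    loop_range: tuple[int, int] = LOOP_RANGE,
    max_len: int = MAX_SEED_LEN,
) -> list[StructureSeed]:
    """Exhaustively enumerate perfect hairpins within geometry bounds.

    A hairpin of stem s and loop l occupies 2s + l consecutive bases with
    pairs (i+k, i+2s+l-1-k) for k < s. This is the built-in suboptimal-
    folding mode: every geometry-admissible fold is a candidate, which is
    tractable because seed length is capped at 30 nt.
    """
    seeds = []
    n = len(sequence)
    for s in range(stem_range[0], stem_range[1] + 1):
        for l in range(loop_range[0], loop_range[1] + 1):
            w = 2 * s + l
            if w > max_len:
                continue
            for i in range(0, n - w + 1):
                ok = all(
                    _pairable(sequence[i + k], sequence[i + w - 1 - k])
                    for k in range(s)
                )
                if ok:
                    seeds.append(
                        StructureSeed(
                            sequence[i : i + w],
                            "(" * s + "." * l + ")" * s,
                            s,
                            l,
                            (transcript_id, offset + i, offset + i + w),
                        )
                    )
    return seeds


@dataclass
class SeedLibrary:
    """Unique hairpin motifs with their occurrence lists."""

    occurrences: dict[tuple[str, str], list[StructureSeed]]

    @property
    def motifs(self) -> list[tuple[str, str]]:
        return list(self.occurrences)

    def __len__(self) -> int:
        return len(self.occurrences)


def build_seed_library(
    transcripts: Sequence[TranscriptRecord],
    stem_range: tuple[int, int] = STEM_RANGE,
    loop_range: tuple[int, int] = LOOP_RANGE,
    max_len: int = MAX_SEED_LEN,
) -> SeedLibrary:
    """Enumerate the hairpin seed library over all 5'UTRs.

    Occurrence coordinates are relative to the 5'UTR start. Duplicate
    (sequence, structure) foldings at the same location are already unique
    by construction; identical motifs at different locations are collected
    as occurrences of one library entry.
    """
    occ: dict[tuple[str, str], list[StructureSeed]] = defaultdict(list)
    any_utr = False
    for rec in transcripts:
        if rec.regions is None:
            continue
        utr = rec.utr5
        if not utr:
            continue
        any_utr = True
        for seed in enumerate_hairpins(
            utr, rec.id, 0, stem_range, loop_range, max_len
        ):
            occ[seed.motif_key].append(seed)
    if not any_utr:
        log.warning("no transcript provided a non-empty 5'UTR; library is empty")
    return SeedLibrary(dict(occ))


# ---------------------------------------------------------------------------
# attention association
# ---------------------------------------------------------------------------


@dataclass
class FootprintScore:
    p_raw: float
    n_occurrences: int
    mean_difference: float
    degenerate: bool = False


def paired_footprint_test(
    footprints: Sequence[tuple[str, int, int]],
    scores_by_transcript: dict[str, np.ndarray],
) -> Optional[FootprintScore]:
    """Paired t-test: contrast inside a footprint vs the rest of the UTR.

    ``footprints`` are (transcript id, start, end) occurrences of one motif.
    One pair per occurrence — (mean score over the occupied positions, mean
    score over the remaining 5'UTR positions of the same transcript). Motifs
    with fewer than 3 usable occurrences are skipped (returns None). When
    every within-pair difference is identical the t statistic is undefined;
    the test then reports p = 0 for a nonzero common difference (flagged
    ``degenerate``) and p = 1 for an all-zero difference.
    """
    inside, outside = [], []
    for tid, start, end in footprints:
        scores = scores_by_transcript.get(tid)
        if scores is None or end > len(scores) or end - start >= len(scores):
            continue
        mask = np.zeros(len(scores), dtype=bool)
        mask[start:end] = True
        inside.append(float(np.mean(scores[mask])))
        outside.append(float(np.mean(scores[~mask])))
    if len(inside) < MIN_OCCURRENCES:
        return None
    diffs = np.array(inside) - np.array(outside)
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return FootprintScore(1.0, len(diffs), 0.0, degenerate=True)
        return FootprintScore(0.0, len(diffs), float(diffs.mean()), degenerate=True)
    t = stats.ttest_rel(inside, outside)
    return FootprintScore(float(t.pvalue), len(diffs), float(diffs.mean()))


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# clustering and association
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}


def one_hot_motifs(
    seeds: Sequence[StructureSeed], pad_to: Optional[int] = None
) -> np.ndarray:
    """One-hot encoding over aligned positions.

    Five channels per position: A/C/G/U plus a paired-position indicator
    taken from the dot-bracket. Motifs are left-aligned and padded with
    zeros to the longest member (or ``pad_to``).
    """
    if not seeds:
        return np.empty((0, 0))
    L = pad_to or max(len(s.sequence) for s in seeds)
    X = np.zeros((len(seeds), L * 5))
    for r, seed in enumerate(seeds):
        for p, (ch, db) in enumerate(zip(seed.sequence, seed.dotbracket)):
            X[r, p * 5 + _BASE_INDEX[ch]] = 1.0
            if db in "()":
                X[r, p * 5 + 4] = 1.0
    return X


@dataclass
class MotifCluster:
    members: list[StructureSeed]
    k: int
    label: int

    @property
    def member_sequences(self) -> list[str]:
        return [m.sequence for m in self.members]

    @property
    def consensus(self) -> str:
        mats = [Counter(chars) for chars in zip(*[
            s.sequence.ljust(max(len(x.sequence) for x in self.members), "-")
            for s in self.members
        ])]
        return "".join(c.most_common(1)[0][0] for c in mats)

    @property
    def consensus_dotbracket(self) -> str:
        db = Counter(m.dotbracket for m in self.members)
        return db.most_common(1)[0][0]


def cluster_significant_motifs(
    significant: Sequence[StructureSeed],
    k_range: tuple[int, int] = (2, 100),
    min_members: int = MIN_CLUSTER_MEMBERS,
) -> list[MotifCluster]:
    """Ward-linkage agglomerative clustering of one-hot motifs at every cut.

    The dendrogram is cut at every k in ``k_range``; clusters with at least
    ``min_members`` members are retained, deduplicated on identical member
    sets across cuts (keeping the smallest k).
    """
    if len(significant) < 2:
        return []
    X = one_hot_motifs(significant)
    Z = linkage(X, method="ward")
    out: list[MotifCluster] = []
    seen: set[frozenset] = set()
    lo, hi = k_range
    for k in range(lo, min(hi, len(significant)) + 1):
        assign = fcluster(Z, t=k, criterion="maxclust")
        for label in np.unique(assign):
            idx = np.nonzero(assign == label)[0]
            if len(idx) < min_members:
                continue
            key = frozenset(idx.tolist())
            if key in seen:
                continue
            seen.add(key)
            out.append(
                MotifCluster([significant[i] for i in idx], k, int(label))
            )
    return out


def test_cluster_association(
    member_labels: Sequence[int],
    background_labels: Sequence[int],
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of cluster membership vs TE class.

    The 2x2 table is (members in high TE, members in low TE, non-member
    significant-seed occurrences in high TE, same in low TE). Returns
    (odds_ratio, p). The odds ratio uses the Haldane 0.5 correction only
    when a cell is zero, for display; the p-value is the uncorrected exact
    test. Raises ValueError when a table margin is zero (association
    undefined).
    """
    a = int(np.sum(np.asarray(member_labels) == 1))
    b = int(np.sum(np.asarray(member_labels) == 0))
    c = int(np.sum(np.asarray(background_labels) == 1))
    d = int(np.sum(np.asarray(background_labels) == 0))
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"zero margin in table {table.tolist()}")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


test_cluster_association.__test__ = False  # library function, not a pytest case


def apic(member_sequences: Sequence[str]) -> float:
    """Average positional information content (bits) of aligned members.

    Members are left-aligned; positions where fewer members align still use
    the observed base frequencies at that position.
    """
    if not member_sequences:
        raise ValueError("empty cluster")
    L = max(len(s) for s in member_sequences)
    padded = [s.ljust(L, "-") for s in member_sequences]
    ic = logo_information_content(padded)
    return float(np.mean(ic))


@dataclass
class MotifAssociation:
    """A reported motif cluster after the full filter chain."""

    cluster: MotifCluster
    p_raw: float
    odds_ratio: float
    direction: str  # "high_TE" | "low_TE"
    apic: float
    member_count: int

    @property
    def consensus(self) -> str:
        return self.cluster.consensus


# ---------------------------------------------------------------------------
# rG4 scanning and scoring
# ---------------------------------------------------------------------------

@dataclass
class RG4Hit:
    transcript_id: str
    start: int
    end: int
    sequence: str
    g_tract_count: int
    loop_lengths: tuple[int, ...]
    gga_repeat: bool
    ggu_repeat: bool
    p_raw: float = float("nan")
    q_bh: float = float("nan")


_RG4_RE = re.compile(r"G{2,}(?:[ACU]{1,7}G{2,}){3,}")


def find_rg4(
    utr5_by_id: dict[str, str] | Sequence[TranscriptRecord],
) -> list[RG4Hit]:
    """Scan 5'UTRs for rG4 candidates.

    Pattern: >= 4 tracts of >= 2 consecutive Gs separated by 1-7 nt
    non-G loops (two stacked G-quartets or more). Greedy left-to-right
    matching yields maximal non-overlapping spans. GGA/GGU repeat character
    is flagged from the loop composition.
    """
    if not isinstance(utr5_by_id, dict):
        utr5_by_id = {
            r.id: r.utr5 for r in utr5_by_id if r.regions is not None and r.utr5
        }
    hits = []
    for tid, seq in utr5_by_id.items():
        for m in _RG4_RE.finditer(seq):
            s = m.group(0)
            tracts = re.findall(r"G{2,}", s)
            loops = re.findall(r"[ACU]{1,7}", s)
            hits.append(
                RG4Hit(
                    tid,
                    m.start(),
                    m.end(),
                    s,
                    len(tracts),
                    tuple(len(l) for l in loops),
                    gga_repeat=all(l == "A" for l in loops) or "GGA" * 2 in s,
                    ggu_repeat=all(l == "U" for l in loops) or "GGU" * 2 in s,
                )
            )
    return hits


def score_rg4(
    hits: Sequence[RG4Hit],
    scores_by_transcript: dict[str, np.ndarray],
    q_threshold: float = SEED_Q_THRESHOLD,
) -> list[RG4Hit]:
    """Score rG4s with the paired inside/outside design, stratified by length.

    Hits sharing one sequence are treated as occurrences of one rG4 motif
    (the paired t-test needs replication); BH correction runs independently
    within each rG4 length stratum. Returns the hits that pass q <
    ``q_threshold``, with p and q filled in.
    """
    by_seq: dict[str, list[RG4Hit]] = defaultdict(list)
    for h in hits:
        by_seq[h.sequence].append(h)

    scored: dict[str, FootprintScore] = {}
    for seq, occs in by_seq.items():
        res = paired_footprint_test(
            [(h.transcript_id, h.start, h.end) for h in occs],
            scores_by_transcript,
        )
        if res is not None:
            scored[seq] = res

    # BH within each length stratum
    by_len: dict[int, list[str]] = defaultdict(list)
    for seq in scored:
        by_len[len(seq)].append(seq)
    q_by_seq: dict[str, float] = {}
    for length, seqs in by_len.items():
        qs = bh_correct([scored[s].p_raw for s in seqs])
        for s, q in zip(seqs, qs):
            q_by_seq[s] = float(q)

    out = []
    for h in hits:
        if h.sequence in q_by_seq:
            h.p_raw = scored[h.sequence].p_raw
            h.q_bh = q_by_seq[h.sequence]
            if h.q_bh < q_threshold and scored[h.sequence].mean_difference > 0:
                out.append(h)
    return out


# ---------------------------------------------------------------------------
# full secondary-structure pipeline
# ---------------------------------------------------------------------------


def discover_structure_motifs(
    transcripts: Sequence[TranscriptRecord],
    scores_by_transcript: dict[str, np.ndarray],
    te_label_by_transcript: dict[str, int],
    k_range: tuple[int, int] = (2, 100),
    min_members: int = MIN_CLUSTER_MEMBERS,
    seed_q: float = SEED_Q_THRESHOLD,
    fisher_p: float = FISHER_P_THRESHOLD,
    min_apic: float = APIC_THRESHOLD,
) -> list[MotifAssociation]:
    """Run the full hairpin-motif discovery chain and return reported motifs.

    Every reported association satisfies: attention q < ``seed_q``, member
    count >= ``min_members``, Fisher p < ``fisher_p``, APIC >= ``min_apic``.
    """
    library = build_seed_library(transcripts)
    keys, results = [], []
    for key, occs in library.occurrences.items():
        res = paired_footprint_test(
            [o.source for o in occs], scores_by_transcript
        )
        if res is not None:
            keys.append(key)
            results.append(res)
    if not results:
        return []
    qs = bh_correct([r.p_raw for r in results])
    significant_keys = {
        key
        for key, r, q in zip(keys, results, qs)
        if q < seed_q and r.mean_difference > 0
    }
    significant = [
        occ
        for key in significant_keys
        for occ in library.occurrences[key]
        if occ.source[0] in te_label_by_transcript
    ]
    if len(significant) < 2:
        return []
    clusters = cluster_significant_motifs(significant, k_range, min_members)

    labels_all = np.array(
        [te_label_by_transcript[s.source[0]] for s in significant]
    )
    reported = []
    for cl in clusters:
        member_set = {id(m) for m in cl.members}
        member_labels = [
            te_label_by_transcript[m.source[0]] for m in cl.members
        ]
        bg_labels = [
            lab
            for s, lab in zip(significant, labels_all)
            if id(s) not in member_set
        ]
        try:
            odds, p = test_cluster_association(member_labels, bg_labels)
        except ValueError as exc:
            log.info("cluster dropped: %s", exc)
            continue
        if p >= fisher_p:
            continue
        a = apic(cl.member_sequences)
        if a < min_apic:
            continue
        direction = "high_TE" if odds > 1 else "low_TE"
        reported.append(
            MotifAssociation(cl, p, odds, direction, a, len(cl.members))
        )
    return reported
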