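"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA via Biopython; genic regions as 3-column TSV (1-based inclusive on
disk) or transcript-coordinate GFF3; Vienna-style dot-bracket companion
files; TSV count tables and TE label tables.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .corpus import GenicRegions, TranscriptRecord, normalize_rna

log = logging.getLogger(__name__)

_GFF_TYPES = {
    "five_prime_UTR": "utr5",
    "CDS": "cds",
    "three_prime_UTR": "utr3",
}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file to an id -> RNA sequence map (T normalized to U)."""
    return {
        rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_regions_tsv(path: str | Path) -> dict[str, GenicRegions]:
    """Read region intervals from TSV with columns

    ``id  utr5_start  utr5_end  cds_start  cds_end  utr3_start  utr3_end``

    in 1-based inclusive coordinates; an empty interval is encoded as
    start > end (e.g. ``1 0``). Converted to 0-based half-open internally.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, GenicRegions] = {}
    for row in df.itertuples(index=False):
        vals = [int(v) for v in row[1:7]]

        def conv(s: int, e: int) -> tuple[int, int]:
            return (s - 1, e) if e >= s else (s - 1, s - 1)

        out[str(row[0])] = GenicRegions(
            conv(vals[0], vals[1]), conv(vals[2], vals[3]), conv(vals[4], vals[5])
        )
    return out


def write_regions_tsv(
    regions: dict[str, GenicRegions], path: str | Path
) -> None:
    rows = []
    for tid, reg in regions.items():
        row: list = [tid]
        for lo, hi in (reg.utr5, reg.cds, reg.utr3):
            row.extend([lo + 1, hi])  # 1-based inclusive; empty -> start > end
        rows.append(row)
    pd.DataFrame(
        rows,
        columns=[
            "id", "utr5_start", "utr5_end", "cds_start", "cds_end",
            "utr3_start", "utr3_end",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_regions_gff3(path: str | Path) -> dict[str, GenicRegions]:
    """Read transcript-coordinate GFF3 where seqid is the transcript id and
    feature types are five_prime_UTR / CDS / three_prime_UTR."""
    spans: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5 or f[2] not in _GFF_TYPES:
                continue
            tid, key = f[0], _GFF_TYPES[f[2]]
            start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
            prev = spans.setdefault(tid, {}).get(key)
            if prev is None:
                spans[tid][key] = (start, end)
            else:  # multi-line CDS etc.: take the hull
                spans[tid][key] = (min(prev[0], start), max(prev[1], end))
    out = {}
    for tid, d in spans.items():
        if "cds" not in d:
            log.warning("GFF3: %s has no CDS feature; skipped", tid)
            continue
        cds = d["cds"]
        utr5 = d.get("utr5", (0, cds[0])) if "utr5" in d else (0, cds[0])
        utr3 = d.get("utr3", (cds[1], cds[1]))
        out[tid] = GenicRegions((0, utr5[1]), cds, utr3)
    return out


def assemble_records(
    sequences: dict[str, str],
    regions: Optional[dict[str, GenicRegions]] = None,
) -> list[TranscriptRecord]:
    """Join sequences with (optional) region annotations into records.

    Records whose annotation does not tile the sequence are skipped with a
    warning rather than aborting the whole ingest.
    """
    out = []
    for tid, seq in sequences.items():
        reg = regions.get(tid) if regions else None
        try:
            out.append(TranscriptRecord(tid, seq, reg))
        except ValueError as exc:
            log.warning("skipping %s: %s", tid, exc)
    return out


def write_dotbracket(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Vienna-convention companion file: >id / sequence / structure lines."""
    with open(path, "w") as fh:
        for r in records:
            if r.structure is None:
                raise ValueError(f"{r.id}: no structure to write")
            fh.write(f">{r.id}\n{r.sequence}\n{r.structure}\n")


def read_dotbracket(path: str | Path) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for i in range(0, len(lines), 3):
        out[lines[i].lstrip(">")] = (normalize_rna(lines[i + 1]), lines[i + 2])
    return out


def read_counts_tsv(path: str | Path, value_col: str = "count") -> pd.Series:
    """Two-column TSV (gene id, count) -> Series indexed by gene id."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df[df.columns[1]].values, index=df[df.columns[0]].astype(str))


def write_te_labels(dataset, path: str | Path) -> None:
    pd.DataFrame(
        [(e.id, e.te, "" if e.label is None else e.label) for e in dataset.entries],
        columns=["id", "te", "label"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# analysis exports
# ---------------------------------------------------------------------------


def write_scores_tsv(scores_by_id, calls, path: str | Path) -> None:
    """Per-position contrast scores with z values and call flags.

    ``calls`` is the :class:`~ribolens.interpret.HighAttentionCalls` for the
    same cohort, in the same sequence order as ``scores_by_id`` iteration.
    """
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tscore\tz\tcalled\n")
        for (tid, scores), z, called in zip(
            scores_by_id.items(), calls.z, calls.called
        ):
            called_set = set(called.tolist())
            for pos, (s, zv) in enumerate(zip(scores, z)):
                fh.write(f"{tid}\t{pos}\t{s:.6g}\t{zv:.4f}\t"
                         f"{int(pos in called_set)}\n")


def write_calls_bed(scores_by_id, calls, path: str | Path) -> None:
    """Called high-attention positions merged into BED-like intervals
    (0-based half-open; columns seq_id, start, end)."""
    with open(path, "w") as fh:
        for tid, called in zip(scores_by_id, calls.called):
            run_start = None
            prev = None
            for pos in list(called) + [None]:
                if run_start is None:
                    run_start = pos
                elif pos is None or pos != prev + 1:
                    fh.write(f"{tid}\t{run_start}\t{prev + 1}\n")
                    run_start = pos
                prev = pos


def write_profile_tsv(offsets, mean_scores, counts, path: str | Path) -> None:
    """AUG-anchored meta-profile as TSV (offset, mean_score, n)."""
    pd.DataFrame(
        {"offset": offsets, "mean_score": mean_scores, "n": counts}
    ).to_csv(path, sep="\t", index=False)


def write_seed_library(library, fasta_path: str | Path,
                       dotbracket_path: str | Path) -> None:
    """Seed library as FASTA plus a companion dot-bracket file; entry ids
    carry the first occurrence's source coordinates."""
    with open(fasta_path, "w") as fa, open(dotbracket_path, "w") as db:
        for i, ((seq, struct), occs) in enumerate(library.occurrences.items()):
            tid, start, end = occs[0].source
            name = f"seed{i:05d}|{tid}:{start}-{end}|n={len(occs)}"
            fa.write(f">{name}\n{seq}\n")
            db.write(f">{name}\n{seq}\n{struct}\n")


def write_motif_report(reports, path: str | Path) -> None:
    """Reported motif clusters as TSV."""
    rows = []
    for i, rep in enumerate(reports):
        rows.append({
            "cluster_id": i,
            "k": rep.cluster.k,
            "n_members": rep.member_count,
            "odds_ratio": rep.odds_ratio,
            "fisher_p": rep.p_raw,
            "apic": rep.apic,
            "direction": rep.direction,
            "consensus": rep.consensus,
            "consensus_structure": rep.cluster.consensus_dotbracket,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_rg4_report(hits, path: str | Path) -> None:
    """Scored rG4 hits as BED-like TSV."""
    rows = [{
        "seq_id": h.transcript_id, "start": h.start, "end": h.end,
        "sequence": h.sequence, "g_tracts": h.g_tract_count,
        "loops": ",".join(map(str, h.loop_lengths)),
        "gga_repeat": int(h.gga_repeat), "ggu_repeat": int(h.ggu_repeat),
        "p": h.p_raw, "q": h.q_bh,
    } for h in hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
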