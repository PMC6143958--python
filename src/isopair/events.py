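"""Structural classification of isoform pairs from transcript models.

Given two exon chains of the same gene the classifier names the structural
difference: alternative promoter (differing 5' ends, shared downstream
chain), alternative 3' end (the mirror case), cassette exon (one internal
exon present in exactly one isoform, flanks shared), retained intron (one
intron left unspliced in one isoform), identical, or complex when several
independent differences combine.  All comparisons are strand-aware:
coordinates are mapped into transcription orientation first, so a
minus-strand pair differing at the genomic-rightmost exon is an alternative
promoter event.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import gffutils


class StructuralEventType(str, Enum):
    ALT_PROMOTER = "alt_promoter"
    ALT_3PRIME_END = "alt_3prime_end"
    CASSETTE_EXON = "cassette_exon"
    RETAINED_INTRON = "retained_intron"
    COMPLEX = "complex"
    IDENTICAL = "identical"


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon chain in 1-based inclusive genomic coordinates."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("a transcript needs at least one exon")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s1 > e1 or s2 > e2:
                raise ValueError("exon start must not exceed exon end")
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    def oriented_exons(self) -> list[tuple[int, int]]:
        """Exons in 5'->3' transcription order on a strand-free axis.

        For the minus strand coordinates are negated, so in the returned
        (lo, hi) pairs lo is always the exon's 5' boundary.
        """
        if self.strand == "+":
            return list(self.exons)
        return [(-e, -s) for (s, e) in reversed(self.exons)]


@dataclass(frozen=True)
class EventCall:
    event_type: StructuralEventType
    details: str = ""


def _merge(chain: list[tuple[int, int]], i: int) -> list[tuple[int, int]]:
    return chain[:i] + [(chain[i][0], chain[i + 1][1])] + chain[i + 2:]


def _common_suffix(a: list, b: list) -> int:
    n = 0
    while n < min(len(a), len(b)) and a[-1 - n] == b[-1 - n]:
        n += 1
    return n


def _common_prefix(a: list, b: list) -> int:
    n = 0
    while n < min(len(a), len(b)) and a[n] == b[n]:
        n += 1
    return n


def classify_pair(a: TranscriptModel, b: TranscriptModel,
                  tss_tolerance: int = 50, tes_tolerance: int = 50) -> EventCall:
    """Name the structural difference between two transcript models.

    ``tss_tolerance``/``tes_tolerance`` treat small terminal shifts (<= the
    tolerance, with a shared splice boundary) as the same promoter / 3' end.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"chromosome mismatch: {a.chrom} vs {b.chrom}")
    if a.strand != b.strand:
        raise ValueError(f"strand mismatch: {a.strand} vs {b.strand}")

    ca = a.oriented_exons()
    cb = b.oriented_exons()
    if ca == cb:
        return EventCall(StructuralEventType.IDENTICAL)

    # retained intron: one chain equals the other with two adjacent exons merged
    for x, y, who in ((ca, cb, b), (cb, ca, a)):
        if len(x) == len(y) + 1:
            for i in range(len(x) - 1):
                if _merge(x, i) == y:
                    return EventCall(StructuralEventType.RETAINED_INTRON,
                                     details=f"intron retained in {who.transcript_id}")

    # cassette exon: one internal exon missing from one chain, flanks shared
    for x, y, who in ((ca, cb, a), (cb, ca, b)):
        if len(x) == len(y) + 1:
            for j in range(1, len(x) - 1):
                if x[:j] + x[j + 1:] == y:
                    lo, hi = x[j]
                    return EventCall(StructuralEventType.CASSETTE_EXON,
                                     details=f"exon {abs(lo)}-{abs(hi)} only in {who.transcript_id}")

    p = _common_prefix(ca, cb)
    s = _common_suffix(ca, cb)

    if len(ca) == 1 and len(cb) == 1:
        (lo1, hi1), (lo2, hi2) = ca[0], cb[0]
        tss_same = abs(lo1 - lo2) <= tss_tolerance
        tes_same = abs(hi1 - hi2) <= tes_tolerance
        if tss_same and tes_same:
            return EventCall(StructuralEventType.IDENTICAL, details="terminal shifts within tolerance")
        if tes_same:
            return EventCall(StructuralEventType.ALT_PROMOTER, details="single-exon 5' difference")
        if tss_same:
            return EventCall(StructuralEventType.ALT_3PRIME_END, details="single-exon 3' difference")
        return EventCall(StructuralEventType.COMPLEX, details="both ends differ")

    # only the first exons differ
    if s == len(ca) - 1 and s == len(cb) - 1:
        (lo1, hi1), (lo2, hi2) = ca[0], cb[0]
        if hi1 == hi2:  # shared splice donor into the common chain
            if abs(lo1 - lo2) > tss_tolerance:
                return EventCall(StructuralEventType.ALT_PROMOTER, details="first-exon 5' extension")
            return EventCall(StructuralEventType.IDENTICAL, details="TSS shift within tolerance")
        overlap = max(lo1, lo2) <= min(hi1, hi2)
        if not overlap or abs(lo1 - lo2) > tss_tolerance:
            return EventCall(StructuralEventType.ALT_PROMOTER, details="distinct first exons")
        return EventCall(StructuralEventType.COMPLEX, details="first exons differ at the donor site")

    # only the last exons differ
    if p == len(ca) - 1 and p == len(cb) - 1:
        (lo1, hi1), (lo2, hi2) = ca[-1], cb[-1]
        if lo1 == lo2:  # shared splice acceptor out of the common chain
            if abs(hi1 - hi2) > tes_tolerance:
                return EventCall(StructuralEventType.ALT_3PRIME_END, details="last-exon 3' extension")
            return EventCall(StructuralEventType.IDENTICAL, details="TES shift within tolerance")
        overlap = max(lo1, lo2) <= min(hi1, hi2)
        if not overlap or abs(hi1 - hi2) > tes_tolerance:
            return EventCall(StructuralEventType.ALT_3PRIME_END, details="distinct last exons")
        return EventCall(StructuralEventType.COMPLEX, details="last exons differ at the acceptor site")

    # all differences confined to the 5' prefix (shared downstream chain)
    if p == 0 and s >= 1:
        return EventCall(StructuralEventType.ALT_PROMOTER, details="differing 5' exon block")
    # all differences confined to the 3' suffix (shared upstream chain)
    if s == 0 and p >= 1:
        return EventCall(StructuralEventType.ALT_3PRIME_END, details="differing 3' exon block")
    return EventCall(StructuralEventType.COMPLEX, details="multiple independent differences")


# ---------------------------------------------------------------------------
# transcript-model input / output

def read_transcripts(path: Path | str, fmt: Optional[str] = None) -> list[TranscriptModel]:
    """Read transcript models from a GTF (exon features) or BED12 file.

    The dialect is inferred from the suffix unless ``fmt`` ('gtf' or
    'bed12') is given.  BED12 blocks are converted from 0-based half-open to
    the internal 1-based inclusive convention.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() == ".bed" else "gtf"
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown transcript format {fmt!r}")


def _read_gtf(path: Path) -> list[TranscriptModel]:
    if path.stat().st_size == 0:
        return []
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                            disable_infer_genes=True, disable_infer_transcripts=True)
    chains: dict[str, dict] = {}
    for exon in db.features_of_type("exon", order_by="start"):
        tids = exon.attributes.get("transcript_id")
        if not tids:
            raise ValueError(f"exon at {exon.seqid}:{exon.start} lacks a transcript_id")
        tid = tids[0]
        rec = chains.setdefault(tid, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
        rec["exons"].append((exon.start, exon.end))
    return [TranscriptModel(tid, rec["chrom"], rec["strand"], tuple(rec["exons"]))
            for tid, rec in chains.items()]


def _read_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {line_no}: BED12 needs 12 columns, got {len(fields)}")
            chrom, chrom_start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
            block_count = int(fields[9])
            sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
            starts = [int(v) for v in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(f"line {line_no}: block count mismatch")
            exons = tuple((chrom_start + off + 1, chrom_start + off + size)
                          for off, size in zip(starts, sizes))
            models.append(TranscriptModel(name, chrom, strand, exons))
    return models


def write_bed12(models: Sequence[TranscriptModel], path: Path | str) -> None:
    """Write transcript models as BED12 (coordinates back to 0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in models:
            chrom_start = m.exons[0][0] - 1
            chrom_end = m.exons[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in m.exons)
            offsets = ",".join(str(s - 1 - chrom_start) for s, _ in m.exons)
            fh.write("\t".join(map(str, [
                m.chrom, chrom_start, chrom_end, m.transcript_id, 0, m.strand,
                chrom_start, chrom_end, 0, len(m.exons), sizes, offsets])) + "\n")
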