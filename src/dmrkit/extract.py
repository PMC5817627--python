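"""Per-CpG methylation count extraction from bisulfite alignments.

Reads Bismark-dialect SAM/BAM (per-read methylation-call tag ``XM``,
conversion-strand tag ``XG``) and tabulates methylated/unmethylated counts
at each CpG site.  Coordinates are taken from the alignment itself, so CpG
sites created by sample variants or indels ("novel" sites absent from the
reference) are counted at their reference positions.  The two strands of a
CpG are merged: calls from GA-conversion reads sit on the guanine and are
shifted one base left onto the forward-strand cytosine.

Also extracts per-read joint methylation patterns ("methylation linkage")
over user-specified genomic intervals.
"""

from __future__ import annotations

import sys
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

# Bismark XM-tag characters in CpG context
_CPG_CALLS = frozenset("zZ")

# CIGAR op codes (pysam numbering)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)
_QUERY_OPS = {_OP_M, _OP_I, _OP_S, _OP_EQ, _OP_X}
_ALIGNED_OPS = {_OP_M, _OP_EQ, _OP_X}
_REF_ONLY_OPS = {_OP_D, _OP_N}

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class MalformedRecordError(ValueError):
    """A SAM record violates the format contract (names the offending read)."""


@dataclass
class AlignedRead:
    """One mapped bisulfite read with its methylation-call string.

    ``pos`` is the 1-based leftmost reference position.  ``call_string``
    has one character per query base consumed by the CIGAR; CpG-context
    characters are 'z' (unmethylated) and 'Z' (methylated).
    ``conv_strand`` is 'CT' (read from the forward strand, calls on the C)
    or 'GA' (reverse strand, calls on the G of the forward-strand CpG).
    """

    query_name: str
    chrom: str
    pos: int
    flags: int
    cigar: tuple[tuple[int, int], ...]  # (op, length), pysam op codes
    call_string: str
    conv_strand: str

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.call_string):
            raise MalformedRecordError(
                f"read {self.query_name!r}: call string length "
                f"{len(self.call_string)} != query bases in CIGAR ({qlen})"
            )
        if self.conv_strand not in ("CT", "GA"):
            raise MalformedRecordError(
                f"read {self.query_name!r}: unknown conversion strand "
                f"{self.conv_strand!r}"
            )

    @property
    def is_paired(self) -> bool:
        return bool(self.flags & FLAG_PAIRED)

    @property
    def is_read2(self) -> bool:
        return bool(self.flags & FLAG_READ2)


@dataclass(frozen=True, order=True)
class SiteCount:
    """Merged counts at one CpG site (1-based forward-strand C position)."""

    chrom: str
    pos: int
    meth: int
    unmeth: int

    @property
    def total(self) -> int:
        return self.meth + self.unmeth


@dataclass
class LinkagePattern:
    """A joint methylation pattern observed on single reads in an interval.

    ``pattern`` has one character per CpG position observed in the interval:
    'M' methylated, 'u' unmethylated, '-' not covered by the read.
    """

    chrom: str
    start: int
    end: int
    positions: tuple[int, ...]
    pattern: str
    count: int


@dataclass
class ExtractionStats:
    """Attrition bookkeeping for one extraction run."""

    records: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    low_mapq: int = 0
    missing_call_tag: int = 0
    reads_used: int = 0
    calls_on_insertions: int = 0
    calls_on_softclips: int = 0
    calls_dedupped: int = 0
    calls_counted: int = 0

    def summary(self) -> str:
        return (
            f"records={self.records} used={self.reads_used} "
            f"unmapped={self.unmapped} secondary={self.secondary} "
            f"supplementary={self.supplementary} low_mapq={self.low_mapq} "
            f"no_call_tag={self.missing_call_tag} "
            f"calls_counted={self.calls_counted} "
            f"calls_dedupped={self.calls_dedupped} "
            f"calls_dropped_ins={self.calls_on_insertions} "
            f"calls_dropped_clip={self.calls_on_softclips}"
        )


def parse_alignments(
    path: str,
    min_mapq: int = 0,
    stats: ExtractionStats | None = None,
) -> Iterator[AlignedRead]:
    """Stream primary mapped reads from a SAM/BAM file as AlignedReads.

    Unmapped, secondary and supplementary records are skipped and counted;
    reads missing the XM methylation-call tag are skipped with a warning
    counter; a missing/invalid XG tag or a call-string/CIGAR length
    mismatch is a hard error naming the read.
    """
    if stats is None:
        stats = ExtractionStats()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            stats.records += 1
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_secondary:
                stats.secondary += 1
                continue
            if rec.is_supplementary:
                stats.supplementary += 1
                continue
            if min_mapq and rec.mapping_quality < min_mapq:
                stats.low_mapq += 1
                continue
            if not rec.has_tag("XM"):
                stats.missing_call_tag += 1
                continue
            if not rec.has_tag("XG"):
                raise MalformedRecordError(
                    f"read {rec.query_name!r}: missing conversion-strand (XG) tag"
                )
            if rec.cigartuples is None:
                raise MalformedRecordError(
                    f"read {rec.query_name!r}: mapped but no CIGAR"
                )
            stats.reads_used += 1
            yield AlignedRead(
                query_name=rec.query_name,
                chrom=rec.reference_name,
                pos=rec.reference_start + 1,
                flags=rec.flag,
                cigar=tuple((op, n) for op, n in rec.cigartuples),
                call_string=rec.get_tag("XM"),
                conv_strand=rec.get_tag("XG"),
            )


def map_calls_to_reference(
    read: AlignedRead, stats: ExtractionStats | None = None
) -> list[tuple[int, str]]:
    """Assign each CpG-context call its reference coordinate via the CIGAR.

    M/=/X ops consume query and reference; I/S consume query only (their
    CpG calls have no reference coordinate and are dropped with a counter);
    D/N consume reference only.  Calls in other contexts (x/X/h/H/u/U/.)
    are ignored.  Because coordinates come from the alignment, CpG sites
    created by deletions or variants are emitted at their reference
    positions even when the reference has no CpG there.
    """
    out: list[tuple[int, str]] = []
    ref = read.pos
    q = 0
    calls = read.call_string
    for op, n in read.cigar:
        if op in _ALIGNED_OPS:
            for i in range(n):
                c = calls[q + i]
                if c in _CPG_CALLS:
                    out.append((ref + i, c))
            ref += n
            q += n
        elif op == _OP_I or op == _OP_S:
            if stats is not None:
                dropped = sum(1 for c in calls[q : q + n] if c in _CPG_CALLS)
                if op == _OP_I:
                    stats.calls_on_insertions += dropped
                else:
                    stats.calls_on_softclips += dropped
            q += n
        elif op in _REF_ONLY_OPS:
            ref += n
        elif op == _OP_H or op == _OP_P:
            pass
        else:
            raise MalformedRecordError(
                f"read {read.query_name!r}: unsupported CIGAR op code {op}"
            )
    return out


def assign_strand(call_position: int, conv_strand: str) -> int:
    """Canonicalize a call position onto the forward-strand C of its CpG.

    CT-strand calls already sit on the C; GA-strand calls sit on the G,
    one base to the right, so they are shifted by -1.
    """
    if conv_strand == "CT":
        return call_position
    if conv_strand == "GA":
        return call_position - 1
    raise MalformedRecordError(f"unknown conversion strand {conv_strand!r}")


def _canonical_calls(
    read: AlignedRead, stats: ExtractionStats | None = None
) -> list[tuple[int, bool]]:
    """(canonical position, is_methylated) pairs for one read."""
    return [
        (assign_strand(pos, read.conv_strand), call == "Z")
        for pos, call in map_calls_to_reference(read, stats)
    ]


def tabulate_counts(
    reads: Iterable[AlignedRead],
    dedup_overlap: bool = True,
    chrom_order: Sequence[str] | None = None,
    stats: ExtractionStats | None = None,
) -> list[SiteCount]:
    """Tabulate merged per-CpG counts for one sample.

    Counts are summed per canonical site and sorted by chromosome (header
    order when given, else first-seen order) then position.  With
    ``dedup_overlap`` the overlapping portion of the second-in-pair mate
    contributes no calls, so an overlapped fragment position is counted
    once.  Mates are matched by query name regardless of file order.
    """
    if stats is None:
        stats = ExtractionStats()
    counts: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0])
    seen_chroms: list[str] = []
    seen_set: set[str] = set()
    # pending first-seen mate of a pair: qname -> (chrom, calls, is_read2)
    pending: dict[str, tuple[str, list[tuple[int, bool]], bool]] = {}

    def commit(chrom: str, calls: Iterable[tuple[int, bool]]) -> None:
        if chrom not in seen_set:
            seen_set.add(chrom)
            seen_chroms.append(chrom)
        for pos, meth in calls:
            cell = counts[(chrom, pos)]
            cell[0 if meth else 1] += 1
            stats.calls_counted += 1

    for read in reads:
        calls = _canonical_calls(read, stats)
        if dedup_overlap and read.is_paired:
            qn = read.query_name
            if qn not in pending:
                pending[qn] = (read.chrom, calls, read.is_read2)
                continue
            chrom1, calls1, first_is_r2 = pending.pop(qn)
            # clip the read2 mate's calls at positions its mate delivered
            if first_is_r2 and not read.is_read2:
                r1_chrom, r1_calls = read.chrom, calls
                r2_chrom, r2_calls = chrom1, calls1
            else:
                r1_chrom, r1_calls = chrom1, calls1
                r2_chrom, r2_calls = read.chrom, calls
            commit(r1_chrom, r1_calls)
            covered = {p for p, _ in r1_calls} if r1_chrom == r2_chrom else set()
            kept = [(p, m) for p, m in r2_calls if p not in covered]
            stats.calls_dedupped += len(r2_calls) - len(kept)
            commit(r2_chrom, kept)
        else:
            commit(read.chrom, calls)

    # mates whose partner never appeared count in full
    for chrom, calls, _ in pending.values():
        commit(chrom, calls)

    order = chrom_order if chrom_order is not None else seen_chroms
    rank = {c: i for i, c in enumerate(order)}
    out = [
        SiteCount(chrom, pos, meth, unmeth)
        for (chrom, pos), (meth, unmeth) in counts.items()
        if meth + unmeth >= 1
    ]
    out.sort(key=lambda s: (rank.get(s.chrom, len(rank)), s.chrom, s.pos))
    return out


def extract_linkage_patterns(
    reads: Iterable[AlignedRead],
    intervals: Sequence[tuple[str, int, int]],
) -> list[LinkagePattern]:
    """Tally per-read joint methylation patterns over genomic intervals.

    Intervals are 1-based inclusive.  Each read covering at least one CpG
    position inside an interval contributes one pattern over the
    interval's observed CpG positions; positions the read does not cover
    are '-'.  Identical patterns are tallied.
    """
    for chrom, start, end in intervals:
        if start > end:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
    # per interval: list of per-read {pos: methylated}
    per_read: dict[int, list[dict[int, bool]]] = {i: [] for i in range(len(intervals))}
    positions: dict[int, set[int]] = {i: set() for i in range(len(intervals))}
    for read in reads:
        calls = _canonical_calls(read)
        if not calls:
            continue
        for i, (chrom, start, end) in enumerate(intervals):
            if read.chrom != chrom:
                continue
            inside = {p: m for p, m in calls if start <= p <= end}
            if inside:
                per_read[i].append(inside)
                positions[i].update(inside)
    out: list[LinkagePattern] = []
    for i, (chrom, start, end) in enumerate(intervals):
        pos_sorted = tuple(sorted(positions[i]))
        if not pos_sorted:
            continue
        tally: Counter[str] = Counter()
        for inside in per_read[i]:
            pattern = "".join(
                ("M" if inside[p] else "u") if p in inside else "-"
                for p in pos_sorted
            )
            tally[pattern] += 1
        for pattern, count in sorted(tally.items()):
            out.append(LinkagePattern(chrom, start, end, pos_sorted, pattern, count))
    return out


def extract_sample(
    path: str,
    dedup_overlap: bool = True,
    min_mapq: int = 0,
    threads: int = 1,
    log: bool = False,
) -> tuple[list[SiteCount], ExtractionStats]:
    """Full extraction for one alignment file: parse, walk, merge, sort.

    ``threads`` only parallelizes BAM decompression; the output is
    identical for any value.
    """
    stats = ExtractionStats()
    with pysam.AlignmentFile(path, check_sq=False, threads=threads) as fh:
        chrom_order = list(fh.references)
    reads = parse_alignments(path, min_mapq=min_mapq, stats=stats)
    counts = tabulate_counts(
        reads, dedup_overlap=dedup_overlap, chrom_order=chrom_order, stats=stats
    )
    if log:
        print(f"[extract] {path}: {stats.summary()}", file=sys.stderr)
    return counts, stats
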