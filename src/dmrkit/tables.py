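"""Tab-delimited table formats shared by the pipeline stages.

All tabular coordinates are 1-based inclusive; BED files are 0-based
half-open and converted only at the BED boundary.  Every format is
self-describing (header line) and round-trips through its reader/writer.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .extract import LinkagePattern, SiteCount

COUNT_COLUMNS = ["chrom", "pos", "total", "meth", "unmeth"]


class TableFormatError(ValueError):
    """A table violates its schema; message carries file and line number."""


def write_count_table(counts: Sequence[SiteCount], path: str) -> None:
    """Write a per-sample CpG count table (chrom, pos, total, meth, unmeth)."""
    with open(path, "w") as fh:
        fh.write("\t".join(COUNT_COLUMNS) + "\n")
        for s in counts:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.meth + s.unmeth}\t{s.meth}\t{s.unmeth}\n")


def write_coverage_table(counts: Sequence[SiteCount], path: str) -> None:
    """Bismark-coverage-style output: chrom, start, end, percent, meth, unmeth."""
    with open(path, "w") as fh:
        for s in counts:
            pct = 100.0 * s.meth / (s.meth + s.unmeth)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos}\t{pct:g}\t{s.meth}\t{s.unmeth}\n")


def read_count_table(path: str) -> list[SiteCount]:
    """Read and validate a count table written by :func:`write_count_table`."""
    out: list[SiteCount] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != COUNT_COLUMNS:
            raise TableFormatError(f"{path}:1: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise TableFormatError(f"{path}:{lineno}: expected 5 columns")
            chrom, pos, total, meth, unmeth = fields
            pos_i, total_i, meth_i, unmeth_i = map(int, (pos, total, meth, unmeth))
            if pos_i < 1 or meth_i < 0 or unmeth_i < 0 or meth_i + unmeth_i != total_i:
                raise TableFormatError(f"{path}:{lineno}: inconsistent counts")
            out.append(SiteCount(chrom, pos_i, meth_i, unmeth_i))
    return out


def validate_count_table(path: str) -> None:
    """Schema + sortedness check; raises TableFormatError with the first bad line."""
    counts = read_count_table(path)
    last: tuple[str, int] | None = None
    chrom_seen: set[str] = set()
    for i, s in enumerate(counts):
        if s.total < 1:
            raise TableFormatError(f"{path}:{i + 2}: zero-coverage site")
        if last is not None:
            if s.chrom == last[0]:
                if s.pos <= last[1]:
                    raise TableFormatError(
                        f"{path}:{i + 2}: positions out of order ({s.pos} after {last[1]})"
                    )
            elif s.chrom in chrom_seen:
                raise TableFormatError(f"{path}:{i + 2}: chromosome {s.chrom} repeats")
        chrom_seen.add(s.chrom)
        last = (s.chrom, s.pos)


def write_linkage_report(patterns: Sequence[LinkagePattern], path: str) -> None:
    """Linkage-pattern report: interval, CpG positions, pattern, read count."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpositions\tpattern\tcount\n")
        for p in patterns:
            pos = ",".join(map(str, p.positions))
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{pos}\t{p.pattern}\t{p.count}\n")


def read_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    """Read BED (0-based half-open) as 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end <= start:
                raise TableFormatError(f"{path}:{lineno}: bad BED interval")
            out.append((chrom, start + 1, end))
    return out


def region_table_to_frame(regions, samples: Sequence[str]) -> pd.DataFrame:
    """Region list -> DataFrame with per-sample N, X and X/N columns."""
    rows = []
    for r in regions:
        row: dict = {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "CpG": len(r.sites),
        }
        for s in samples:
            n = r.N[s]
            x = r.X[s]
            row[f"{s}:N"] = n
            row[f"{s}:X"] = x
            row[f"{s}:frac"] = x / n if n > 0 else float("nan")
        rows.append(row)
    columns = ["chrom", "start", "end", "CpG"] + [
        f"{s}:{f}" for s in samples for f in ("N", "X", "frac")
    ]
    return pd.DataFrame(rows, columns=columns)


def write_region_table(regions, samples: Sequence[str], path: str) -> None:
    frame = region_table_to_frame(regions, samples)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_region_table(path: str) -> pd.DataFrame:
    """Read a region table; returns the frame plus its sample names."""
    frame = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "CpG"]
    if list(frame.columns[:4]) != required:
        raise TableFormatError(f"{path}: expected leading columns {required}")
    return frame


def region_table_samples(frame: pd.DataFrame) -> list[str]:
    samples = []
    for col in frame.columns:
        if col.endswith(":N"):
            samples.append(col[:-2])
    return samples


def write_dmr_table(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dmr_bed(frame: pd.DataFrame, path: str) -> None:
    """Export flagged DMR intervals as BED (1-based inclusive -> 0-based half-open)."""
    dmr_cols = [c for c in frame.columns if c.endswith(":dmr")]
    with open(path, "w") as fh:
        for _, row in frame.iterrows():
            if any(row[c] is True or row[c] == True for c in dmr_cols):  # noqa: E712
                fh.write(f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\n")
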