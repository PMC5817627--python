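"""Grouping CpG sites into candidate regions.

Per-sample count tables are joined into a site-by-sample matrix, sites
meeting a minimum-coverage rule are kept, and valid sites are grouped by
single-linkage clustering on genomic distance.  Pure single-linkage
suffers from chaining — a run of closely spaced sites can fuse loci that
are far apart — so any cluster whose span exceeds a length cap is split
recursively at its largest internal gap.  Clustering never looks at
methylation levels, only at coverage and position, so it cannot bias the
downstream differential tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the clustering stage.

    min_reads:   per-site per-sample coverage minimum (r)
    min_samples: number of samples that must meet min_reads (s)
    max_dist:    maximum gap in bp joining adjacent valid sites (d)
    min_cpg:     minimum CpG sites per region (c)
    max_len:     maximum region span in bp before splitting (x)
    min_total:   minimum summed meth+unmeth per sample per region (m)
    """

    min_reads: int = 3
    min_samples: int = 1
    max_dist: int = 100
    min_cpg: int = 3
    max_len: int = 500
    min_total: int = 20

    def __post_init__(self) -> None:
        for name in ("min_reads", "min_samples", "min_cpg", "min_total"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_dist < 1 or self.max_len < 1:
            raise ValueError("max_dist and max_len must be >= 1")


#: Parameters reproducing plain 100-bp single-linkage clustering with a
#: 5-site minimum and no span cap or count filters (BiSeq-style clusters).
BISEQ_PRESET = ClusterParams(
    min_reads=1, min_samples=1, max_dist=100, min_cpg=5, max_len=10**9, min_total=1
)

PRESETS: Mapping[str, ClusterParams] = {"biseq": BISEQ_PRESET}


@dataclass
class SiteMatrix:
    """Sorted per-CpG counts across samples.

    ``frame`` is indexed by (chrom, pos) with two columns per sample,
    ``<sample>:meth`` and ``<sample>:unmeth``; absent cells are NaN.
    ``chrom_order`` fixes output ordering (first-seen input order).
    """

    frame: pd.DataFrame
    samples: list[str]
    chrom_order: list[str]

    def coverage(self) -> pd.DataFrame:
        """Per-site per-sample coverage (meth+unmeth); NaN where absent."""
        cov = {}
        for s in self.samples:
            cov[s] = self.frame[f"{s}:meth"] + self.frame[f"{s}:unmeth"]
        return pd.DataFrame(cov, index=self.frame.index)


@dataclass
class Region:
    """A cluster of CpG sites with per-sample aggregated counts.

    start/end are the 1-based positions of the first and last member CpG.
    X is summed methylated, N summed total coverage over member sites.
    """

    chrom: str
    sites: tuple[int, ...]
    X: dict[str, int]
    N: dict[str, int]

    @property
    def start(self) -> int:
        return self.sites[0]

    @property
    def end(self) -> int:
        return self.sites[-1]

    @property
    def span(self) -> int:
        return self.end - self.start


def join_samples(tables: Mapping[str, Sequence]) -> SiteMatrix:
    """Full outer join of per-sample count tables on (chrom, pos).

    Each input table must be sorted and unique per site (hard error
    otherwise).  Chromosome order follows first appearance across inputs.
    """
    samples = list(tables)
    chrom_order: list[str] = []
    frames = []
    for name, counts in tables.items():
        seen: set[tuple[str, int]] = set()
        last: tuple[str, int] | None = None
        chroms_done: set[str] = set()
        for c in counts:
            key = (c.chrom, c.pos)
            if key in seen:
                raise ValueError(f"sample {name!r}: duplicate site {key}")
            seen.add(key)
            if last is not None and c.chrom == last[0] and c.pos <= last[1]:
                raise ValueError(f"sample {name!r}: unsorted at {key}")
            if last is not None and c.chrom != last[0] and c.chrom in chroms_done:
                raise ValueError(f"sample {name!r}: chromosome {c.chrom} repeats")
            if last is not None and c.chrom != last[0]:
                chroms_done.add(last[0])
            last = key
            if c.chrom not in chrom_order:
                chrom_order.append(c.chrom)
        frame = pd.DataFrame(
            {
                f"{name}:meth": [c.meth for c in counts],
                f"{name}:unmeth": [c.unmeth for c in counts],
            },
            index=pd.MultiIndex.from_arrays(
                [[c.chrom for c in counts], [c.pos for c in counts]],
                names=["chrom", "pos"],
            ),
            dtype=float,
        )
        frames.append(frame)
    joined = pd.concat(frames, axis=1, join="outer") if frames else pd.DataFrame()
    if len(joined):
        rank = {c: i for i, c in enumerate(chrom_order)}
        key = [(rank[c], p) for c, p in joined.index]
        joined = joined.iloc[sorted(range(len(key)), key=key.__getitem__)]
    return SiteMatrix(joined, samples, chrom_order)


def split_matrix(matrix: SiteMatrix) -> dict[str, list]:
    """Inverse of join_samples: per-sample sorted count tables (round-trip)."""
    from .extract import SiteCount

    out: dict[str, list[SiteCount]] = {s: [] for s in matrix.samples}
    for (chrom, pos), row in matrix.frame.iterrows():
        for s in matrix.samples:
            meth = row[f"{s}:meth"]
            unmeth = row[f"{s}:unmeth"]
            if not (np.isnan(meth) or np.isnan(unmeth)):
                out[s].append(SiteCount(chrom, int(pos), int(meth), int(unmeth)))
    return out


def filter_valid_sites(matrix: SiteMatrix, params: ClusterParams) -> SiteMatrix:
    """Keep sites where >= min_samples samples have coverage >= min_reads.

    Only coverage is consulted, never the meth/unmeth split.
    """
    if not len(matrix.frame):
        return matrix
    cov = matrix.coverage()
    ok = (cov >= params.min_reads).sum(axis=1) >= params.min_samples
    return SiteMatrix(matrix.frame[ok], matrix.samples, matrix.chrom_order)


def single_linkage(positions: Sequence[int], max_dist: int) -> list[list[int]]:
    """Single-linkage clusters of sorted positions: cut at every gap > max_dist."""
    pos = np.asarray(positions)
    if pos.size == 0:
        return []
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    cuts = np.flatnonzero(np.diff(pos) > max_dist) + 1
    return [chunk.tolist() for chunk in np.split(pos, cuts)]


def split_oversized(positions: Sequence[int], max_len: int) -> list[list[int]]:
    """Recursively split a cluster at its largest internal gap (leftmost on
    ties) until every sub-cluster spans <= max_len bp."""
    pos = list(positions)
    if len(pos) <= 1 or pos[-1] - pos[0] <= max_len:
        return [pos]
    gaps = np.diff(pos)
    cut = int(np.argmax(gaps)) + 1  # argmax takes the leftmost maximum
    return split_oversized(pos[:cut], max_len) + split_oversized(pos[cut:], max_len)


def build_regions(matrix: SiteMatrix, params: ClusterParams) -> list[Region]:
    """Cluster valid sites into regions and apply per-region filters.

    Pipeline: single-linkage at max_dist -> split oversized clusters ->
    drop clusters with fewer than min_cpg sites -> aggregate per-sample
    X and N over member sites (missing cells contribute zero) -> drop
    regions where any sample's N < min_total.
    """
    regions: list[Region] = []
    if not len(matrix.frame):
        return regions
    meth = matrix.frame[[f"{s}:meth" for s in matrix.samples]].fillna(0)
    meth.columns = matrix.samples
    unmeth = matrix.frame[[f"{s}:unmeth" for s in matrix.samples]].fillna(0)
    unmeth.columns = matrix.samples
    total = meth + unmeth
    for chrom in matrix.chrom_order:
        try:
            sub = matrix.frame.xs(chrom, level="chrom", drop_level=False)
        except KeyError:
            continue
        positions = [int(p) for _, p in sub.index]
        for cluster in single_linkage(positions, params.max_dist):
            for piece in split_oversized(cluster, params.max_len):
                if len(piece) < params.min_cpg:
                    continue
                idx = [(chrom, p) for p in piece]
                X = meth.loc[idx].sum()
                N = total.loc[idx].sum()
                region = Region(
                    chrom=chrom,
                    sites=tuple(piece),
                    X={s: int(X[s]) for s in matrix.samples},
                    N={s: int(N[s]) for s in matrix.samples},
                )
                if any(region.N[s] < params.min_total for s in matrix.samples):
                    continue
                regions.append(region)
    return regions
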