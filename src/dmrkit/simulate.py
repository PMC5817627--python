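"""Synthetic data generators for every pipeline boundary.

Three levels are covered, each with full ground-truth bookkeeping so the
pipeline's outputs can be checked exactly:

* a toy reference chromosome with CpG dinucleotides at known positions
  (and, optionally, C-A-G loci where a one-base deletion in the reads
  creates a novel CpG absent from the reference);
* Bismark-dialect SAM reads carrying per-base methylation-call strings
  (XM tag, 'z'/'Z' in CpG context) and conversion-strand tags (XG),
  including paired mates with overlapping spans and deletion-carrying
  reads over the novel loci;
* replicate-level region count tables drawn from a beta-binomial with
  controlled group means, dispersion and coverage, with optional injected
  methylation differences on a labelled subset of regions.

Bisulfite-conversion failure and sequencing error are not modelled
separately; they are absorbed into the per-site methylation
probabilities.  All outputs are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extract import (
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
)

_BASES = np.array(list("ACGT"))


@dataclass
class Reference:
    """A simulated chromosome with its known CpG positions (1-based C)."""

    chrom: str
    seq: str
    cpg_positions: list[int]
    novel_sites: list[int]  # C positions of planted C-A-G loci (no reference CpG)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ReadSimConfig:
    """Knobs of the read-level simulation.

    ``meth_prob`` maps each sample to its per-site methylation
    probability: a scalar applied to all CpG sites, or one value per
    reference CpG site.  ``dmr_window`` optionally overrides the
    probability inside a genomic window per sample, to engineer a
    differentially methylated region.  ``novel_sites`` positions receive
    dedicated unpaired reads carrying a 1-bp deletion that turns the
    planted C-A-G into a CpG in the read.
    """

    seed: int
    chrom: str = "chr1"
    length: int = 20_000
    cpg_density: float = 0.02  # expected CpGs per bp
    meth_prob: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"s1": 0.5}
    )
    n_reads: int = 2_000  # per sample
    read_length: int = 80
    paired_fraction: float = 0.5
    ga_fraction: float = 0.5  # reads simulated from the reverse (GA) strand
    novel_sites: tuple[int, ...] = ()
    novel_read_depth: int = 6
    dmr_window: tuple[int, int, Mapping[str, float]] | None = None


def make_reference(config: ReadSimConfig) -> Reference:
    """Build a toy chromosome with CpGs at recorded positions.

    The background sequence is drawn base by base, never allowing an
    accidental C-G dinucleotide; CG pairs are then planted at positions
    drawn from the configured density (geometric gaps, minimum 2 bp), so
    the recorded list is exactly the set of CG dinucleotides.  Requested
    novel-site loci are planted as C-A-G, which is not a CpG in the
    reference but becomes one when a read deletes the A.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.length
    seq = rng.choice(4, size=n)
    # rewrite any background CG into CA
    for i in range(n - 1):
        if seq[i] == 1 and seq[i + 1] == 2:
            seq[i + 1] = 0
    cpg: list[int] = []
    if config.cpg_density > 0:
        pos = 2  # 0-based index of the C; keep one base of margin
        mean_gap = max(1.0 / config.cpg_density, 2.0)
        reserved = set()
        for p in config.novel_sites:
            reserved.update(range(p - 3, p + 4))
        while True:
            pos += 2 + rng.geometric(1.0 / mean_gap)
            if pos >= n - 2:
                break
            if any((pos + d) in reserved for d in (-1, 0, 1)):
                continue
            seq[pos] = 1
            seq[pos + 1] = 2
            cpg.append(pos + 1)  # 1-based C position
    for p in config.novel_sites:
        if not 2 <= p <= n - 2:
            raise ValueError(f"novel site {p} outside reference")
        seq[p - 1] = 1  # C at 1-based p
        seq[p] = 0  # A
        seq[p + 1] = 2  # G
    ref_seq = "".join(_BASES[seq])
    # planting novel loci may have destroyed a background CpG: rescan
    cpg = [i + 1 for i in range(n - 1) if ref_seq[i : i + 2] == "CG"]
    return Reference(config.chrom, ref_seq, cpg, list(config.novel_sites))


@dataclass
class SamRead:
    qname: str
    flag: int
    pos: int  # 1-based
    cigar: str
    seq: str
    xm: str
    xg: str
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0

    def to_line(self, chrom: str) -> str:
        return "\t".join(
            [
                self.qname,
                str(self.flag),
                chrom,
                str(self.pos),
                "40",
                self.cigar,
                self.rnext,
                str(self.pnext),
                str(self.tlen),
                self.seq,
                "I" * len(self.seq),
                f"XM:Z:{self.xm}",
                f"XG:Z:{self.xg}",
            ]
        )


def _site_probs(
    config: ReadSimConfig, reference: Reference, sample: str
) -> dict[int, float]:
    """Per-CpG methylation probability for one sample, novel loci included."""
    spec = config.meth_prob[sample]
    sites = reference.cpg_positions + reference.novel_sites
    if np.isscalar(spec):
        probs = {p: float(spec) for p in sites}
    else:
        values = list(spec)
        if len(values) != len(reference.cpg_positions):
            raise ValueError("per-site probabilities must match the CpG list")
        probs = dict(zip(reference.cpg_positions, map(float, values)))
        probs.update({p: 0.5 for p in reference.novel_sites})
    if config.dmr_window is not None:
        start, end, by_sample = config.dmr_window
        if sample in by_sample:
            for p in sites:
                if start <= p <= end:
                    probs[p] = float(by_sample[sample])
    return probs


def _read_record(
    qname: str,
    flag: int,
    start: int,  # 1-based
    length: int,
    reference: Reference,
    calls: Mapping[int, bool],  # canonical C position -> methylated
    xg: str,
) -> SamRead:
    """Assemble one ungapped read; XM marks CpG calls at covered sites."""
    span = range(start, start + length)
    xm = []
    seq = []
    for pos in span:
        base = reference.seq[pos - 1]
        call_pos = pos if xg == "CT" else pos - 1  # GA reads carry the call on the G
        if call_pos in calls and (
            (xg == "CT" and base == "C") or (xg == "GA" and base == "G")
        ):
            meth = calls[call_pos]
            xm.append("Z" if meth else "z")
            if xg == "CT":
                seq.append("C" if meth else "T")
            else:
                seq.append("G" if meth else "A")
        else:
            xm.append(".")
            seq.append(base)
    return SamRead(qname, flag, start, f"{length}M", "".join(seq), "".join(xm), xg)


def simulate_reads(
    config: ReadSimConfig,
    reference: Reference,
    sample: str,
) -> tuple[list[str], dict[int, list[int]]]:
    """Simulate one sample's SAM records and its delivered-call truth table.

    Returns (SAM lines without header, truth) where truth maps canonical
    CpG position -> [methylated, unmethylated] call counts as they should
    appear after extraction with mate-overlap deduplication: a paired
    fragment's methylation state is drawn once per site, both mates
    report it, and the overlap is counted once.
    """
    sample_index = sorted(config.meth_prob).index(sample)
    rng = np.random.default_rng([config.seed, 2, sample_index])
    probs = _site_probs(config, reference, sample)
    # regular reads call only reference CpGs; novel loci are covered by the
    # dedicated deletion-carrying reads below
    cpg = np.array(sorted(set(probs) - set(reference.novel_sites)), dtype=int)
    truth: dict[int, list[int]] = {}
    lines: list[str] = []

    def deliver(pos: int, meth: bool) -> None:
        cell = truth.setdefault(pos, [0, 0])
        cell[0 if meth else 1] += 1

    rl = config.read_length
    max_start = reference.length - 2 * rl - 1
    for i in range(config.n_reads):
        qname = f"{sample}.r{i}"
        start = int(rng.integers(1, max_start))
        xg = "GA" if rng.random() < config.ga_fraction else "CT"
        paired = rng.random() < config.paired_fraction
        if not paired:
            lo, hi = start, start + rl - 1
            if xg == "CT":
                covered = cpg[(cpg >= lo) & (cpg <= hi)]
            else:  # the call sits on the G at p+1
                covered = cpg[(cpg + 1 >= lo) & (cpg + 1 <= hi)]
            calls = {int(p): bool(rng.random() < probs[int(p)]) for p in covered}
            flag = FLAG_REVERSE if xg == "GA" else 0
            lines.append(
                _read_record(qname, flag, start, rl, reference, calls, xg).to_line(
                    config.chrom
                )
            )
            for p, m in calls.items():
                deliver(p, m)
        else:
            # overlapping proper pair: fragment shorter than two read lengths
            frag = int(rng.integers(rl + rl // 4, 2 * rl - rl // 4))
            start2 = start + frag - rl
            # one methylation state per fragment per site
            lo, hi = start, start + frag - 1
            if xg == "CT":
                frag_sites = cpg[(cpg >= lo) & (cpg <= hi)]
            else:
                frag_sites = cpg[(cpg + 1 >= lo) & (cpg + 1 <= hi)]
            calls = {int(p): bool(rng.random() < probs[int(p)]) for p in frag_sites}

            def covered_by(s: int) -> set[int]:
                if xg == "CT":
                    return {p for p in calls if s <= p <= s + rl - 1}
                return {p for p in calls if s <= p + 1 <= s + rl - 1}

            cov1 = covered_by(start)
            cov2 = covered_by(start2)
            rev = FLAG_REVERSE if xg == "GA" else 0
            base = FLAG_PAIRED | FLAG_PROPER_PAIR | rev
            r1 = _read_record(
                qname,
                base | FLAG_READ1,
                start,
                rl,
                reference,
                {p: calls[p] for p in cov1},
                xg,
            )
            r2 = _read_record(
                qname,
                base | FLAG_READ2,
                start2,
                rl,
                reference,
                {p: calls[p] for p in cov2},
                xg,
            )
            r1.rnext = r2.rnext = "="
            r1.pnext, r2.pnext = r2.pos, r1.pos
            r1.tlen, r2.tlen = frag, -frag
            lines.append(r1.to_line(config.chrom))
            lines.append(r2.to_line(config.chrom))
            for p in cov1 | cov2:  # overlap delivered once
                deliver(p, calls[p])

    # deletion-carrying reads over the planted C-A-G loci (novel CpG sites)
    for j, p in enumerate(reference.novel_sites):
        for d in range(config.novel_read_depth):
            qname = f"{sample}.novel{j}.{d}"
            start = max(1, p - rl // 2)
            left = p - start + 1  # bases up to and including the C
            right = rl - left
            meth = bool(rng.random() < probs[p])
            xm = "." * (left - 1) + ("Z" if meth else "z") + "." * right
            seq = (
                reference.seq[start - 1 : p - 1]
                + ("C" if meth else "T")
                + reference.seq[p + 1 : p + 1 + right]
            )
            cigar = f"{left}M1D{right}M"
            lines.append(
                SamRead(qname, 0, start, cigar, seq, xm, "CT").to_line(config.chrom)
            )
            deliver(p, meth)
    return lines, truth


def write_sam(
    lines: Sequence[str], chrom: str, length: int, path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for line in lines:
            fh.write(line + "\n")


def simulate_sample_files(
    config: ReadSimConfig, reference: Reference, out_dir: str
) -> tuple[dict[str, str], dict[str, dict[int, list[int]]]]:
    """Write one SAM per sample; returns ({sample: path}, {sample: truth})."""
    import os

    paths: dict[str, str] = {}
    truths: dict[str, dict[int, list[int]]] = {}
    for sample in sorted(config.meth_prob):
        lines, truth = simulate_reads(config, reference, sample)
        path = os.path.join(out_dir, f"{sample}.sam")
        write_sam(lines, config.chrom, reference.length, path)
        paths[sample] = path
        truths[sample] = truth
    return paths, truths


@dataclass
class CountSimConfig:
    """Knobs of the region-count simulation.

    ``groups`` maps group name to replicate count; ``mu`` gives each
    group's mean methylation fraction.  ``phi`` is the beta-binomial
    dispersion (intra-class correlation); coverage per replicate is
    1 + Poisson(mean_coverage - 1).  A ``diff_fraction`` of regions gets
    ``diff_size`` added to the last group's mean (clipped to [0.02,
    0.98]), with truth labels recorded.
    """

    seed: int
    n_regions: int = 1000
    groups: Mapping[str, int] = field(default_factory=lambda: {"A": 2, "B": 2})
    mu: Mapping[str, float] = field(default_factory=lambda: {"A": 0.5, "B": 0.5})
    phi: float = 0.05
    mean_coverage: float = 30.0
    diff_fraction: float = 0.0
    diff_size: float = 0.0

    def sample_names(self) -> dict[str, list[str]]:
        return {g: [f"{g}{i + 1}" for i in range(k)] for g, k in self.groups.items()}


def sample_beta_binomial(
    rng: np.random.Generator,
    n: np.ndarray,
    mu: float | np.ndarray,
    phi: float,
) -> np.ndarray:
    """X ~ BetaBinomial(n, mu, phi) via Beta-then-Binomial composition.

    phi is the intra-class correlation: p ~ Beta(a, b) with
    a + b = (1 - phi) / phi, so Var(p) = mu (1 - mu) phi; phi = 0
    degenerates to Binomial(n, mu).  mu may be a scalar or match n's shape.
    """
    n = np.asarray(n)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), n.shape)
    if phi <= 0.0:
        return rng.binomial(n, mu)
    s = (1.0 - phi) / phi
    p = rng.beta(mu * s, (1.0 - mu) * s, size=n.shape)
    return rng.binomial(n, p)


def simulate_region_counts(
    config: CountSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a region table plus its truth labels.

    Returns (region table in the clustering module's output format,
    truth) where truth has one row per region: ``is_diff`` and each
    group's true mean.
    """
    rng = np.random.default_rng([config.seed, 3])
    names = config.sample_names()
    n_regions = config.n_regions
    n_diff = int(round(config.diff_fraction * n_regions))
    is_diff = np.zeros(n_regions, dtype=bool)
    if n_diff:
        is_diff[rng.choice(n_regions, size=n_diff, replace=False)] = True
    shifted = list(config.groups)[-1]

    rows: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {"is_diff": is_diff}
    spacing = 1000
    rows["chrom"] = np.array(["chr1"] * n_regions)
    rows["start"] = np.arange(1, n_regions + 1) * spacing
    rows["end"] = rows["start"] + 200
    rows["CpG"] = np.full(n_regions, 5)
    for g, reps in config.groups.items():
        mu_vec = np.full(n_regions, float(config.mu[g]))
        if g == shifted and n_diff:
            mu_vec[is_diff] = np.clip(mu_vec[is_diff] + config.diff_size, 0.02, 0.98)
        truth[f"mu_{g}"] = mu_vec
        for sample in names[g]:
            n = 1 + rng.poisson(config.mean_coverage - 1.0, size=n_regions)
            x = sample_beta_binomial(rng, n, mu_vec, config.phi)
            rows[f"{sample}:N"] = n
            rows[f"{sample}:X"] = x
            rows[f"{sample}:frac"] = x / n
    return pd.DataFrame(rows), pd.DataFrame(truth)
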