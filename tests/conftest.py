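import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def sam_factory(tmp_path):
    """Write a SAM file from (header chromosomes, record lines)."""

    def write(records, chroms=(("chr1", 100000),), name="sample.sam"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom, length in chroms:
                fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
            for rec in records:
                fh.write(rec + "\n")
        return str(path)

    return write


def sam_line(
    qname="r1",
    flag=0,
    chrom="chr1",
    pos=100,
    mapq=40,
    cigar="5M",
    seq=None,
    xm=".....",
    xg="CT",
    rnext="*",
    pnext=0,
    tlen=0,
):
    if seq is None:
        seq = "A" * sum(
            int(n) for n, op in _split_cigar(cigar) if op in "MIS=X"
        )
    qual = "I" * len(seq)
    return "\t".join(
        [qname, str(flag), chrom, str(pos), str(mapq), cigar, rnext,
         str(pnext), str(tlen), seq, qual, f"XM:Z:{xm}", f"XG:Z:{xg}"]
    )


def _split_cigar(cigar):
    import re

    return re.findall(r"(\d+)([MIDNSHP=X])", cigar)
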