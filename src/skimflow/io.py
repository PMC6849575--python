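"""Reading and writing of the flat-file formats used throughout the pipeline.

FASTA/FASTQ go through Biopython; SAM is parsed with pysam when a header is
present and falls back to a minimal tab-split parse for the headerless
dialect accepted as input. All coordinates are 0-based half-open in memory
and 1-based on SAM/VCF write.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# SAM flag bits used by the pipeline
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignedRead:
    """One SAM record reduced to the fields the pipeline consumes."""

    qname: str
    flag: int
    ref_id: str
    pos: int  # 0-based leftmost aligned position; -1 if unmapped
    cigar: str
    seq: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED) or self.ref_id == "*"

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER)

    @property
    def is_primary(self) -> bool:
        return not self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY | FLAG_DUP)

    def aligned_pairs(self) -> Iterator[tuple[int, str]]:
        """Yield (reference_pos, read_base) for every aligned base.

        Handles M/=/X (consume both), I/S (read only), D/N (reference only),
        H/P (neither).
        """
        rpos = self.pos
        qpos = 0
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "M=X":
                for k in range(n):
                    yield rpos + k, self.seq[qpos + k]
                rpos += n
                qpos += n
            elif ch in "IS":
                qpos += n
            elif ch in "DN":
                rpos += n
            elif ch in "HP":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {ch!r} in read {self.qname}")

    def aligned_length(self) -> int:
        """Number of read bases aligned to the reference."""
        total = 0
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "M=X":
                    total += int(num)
                num = ""
        return total


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    """Write (name, seq, qual-string) triples as FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_sam(
    records: Iterable[AlignedRead],
    ref_lengths: Mapping[str, int],
    path: str | os.PathLike,
    qual_char: str = "I",
) -> None:
    """Write AlignedRead records as a minimal SAM file (header + 11 fields)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            if r.is_unmapped:
                rname, pos, cigar, mapq = "*", 0, "*", 0
            else:
                rname, pos, cigar, mapq = r.ref_id, r.pos + 1, r.cigar, 60
            qual = qual_char * len(r.seq)
            fh.write(
                f"{r.qname}\t{r.flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{r.seq}\t{qual}\n"
            )


def _parse_sam_line(line: str) -> AlignedRead:
    f = line.rstrip("\n").split("\t")
    if len(f) < 11:
        raise ValueError(f"SAM record with fewer than 11 fields: {line[:80]!r}")
    return AlignedRead(
        qname=f[0],
        flag=int(f[1]),
        ref_id=f[2],
        pos=int(f[3]) - 1,
        cigar=f[5],
        seq=f[9].upper(),
    )


def read_sam(path: str | os.PathLike) -> list[AlignedRead]:
    """Read a SAM file (header optional) into AlignedRead records."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@"):
        out = []
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for a in sam:
                out.append(
                    AlignedRead(
                        qname=a.query_name,
                        flag=a.flag,
                        ref_id=a.reference_name if a.reference_name else "*",
                        pos=a.reference_start if a.reference_start is not None else -1,
                        cigar=a.cigarstring or "*",
                        seq=(a.query_sequence or "").upper(),
                    )
                )
        return out
    with open(path) as fh:
        return [_parse_sam_line(line) for line in fh if line.strip() and not line.startswith("@")]


def phred_string(q: int, n: int) -> str:
    return chr(q + 33) * n
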