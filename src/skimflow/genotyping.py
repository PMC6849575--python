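"""Low-coverage genotyping from read alignments.

The stack mirrors what shallow genome skimming permits: pileups from
proper-pair primary alignments, reference-free SNP discovery, fixed diploid
genotype calls (no genotype likelihoods), and a bespoke filter cascade —
per-sample high-coverage exclusion, the more-than-two-alleles rule,
missing-data thresholds, and a duplicated-region flag — followed by IUPAC
alignment and VCF export.

Internally pileups are dense numpy count arrays (samples x positions x 4
bases), which keeps whole-genome toy datasets fast; the column-stream view
required by the public contract is a thin generator over that array.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io import AlignedRead, read_sam

MISSING = np.int8(-1)

# call codes: 0..3 = A,C,G,T homozygote; 4..9 = IUPAC heterozygote
_BASE_ORDER = "ACGT"
_HET_CODES = "RYSWKM"
_CALL_CHAR = _BASE_ORDER + _HET_CODES
IUPAC_PAIRS = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
HET_SETS = {code: pair for pair, code in IUPAC_PAIRS.items()}
_PAIR_CODE = {}
for _pair, _c in IUPAC_PAIRS.items():
    _a, _b = sorted(_pair)
    _PAIR_CODE[(_BASE_ORDER.index(_a), _BASE_ORDER.index(_b))] = 4 + _HET_CODES.index(_c)


def call_to_char(code: int) -> str:
    return "N" if code == MISSING else _CALL_CHAR[code]


def char_to_call(ch: str) -> np.int8:
    ch = ch.upper()
    if ch in ("N", "-", "?"):
        return MISSING
    return np.int8(_CALL_CHAR.index(ch))


def het_code(base_a: str, base_b: str) -> np.int8:
    a, b = sorted((base_a, base_b))
    return np.int8(4 + _HET_CODES.index(IUPAC_PAIRS[frozenset((a, b))]))


@dataclass
class CoverageStats:
    samples: list[str]
    reference_length: int
    genomewide_mean: np.ndarray  # aligned bases / reference length, per sample
    skipped_records: dict[str, int] = field(default_factory=dict)

    def mean_of(self, sample: str) -> float:
        return float(self.genomewide_mean[self.samples.index(sample)])


@dataclass
class PileupColumn:
    ref_id: str
    pos: int
    counts: dict[str, dict[str, int]]  # sample -> base -> count


@dataclass
class Pileup:
    samples: list[str]
    ref_names: list[str]
    ref_lengths: dict[str, int]
    offsets: dict[str, int]  # ref name -> offset into the concatenated axis
    counts: np.ndarray  # (n_samples, total_length, 4) base counts
    stats: CoverageStats

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def position_of(self, flat: int) -> tuple[str, int]:
        for name in reversed(self.ref_names):
            if flat >= self.offsets[name]:
                return name, flat - self.offsets[name]
        raise IndexError(flat)

    def columns(self) -> Iterator[PileupColumn]:
        """Stream one column per covered position, in coordinate order."""
        covered = np.flatnonzero(self.counts.sum(axis=(0, 2)) > 0)
        for flat in covered:
            ref_id, pos = self.position_of(int(flat))
            col = {}
            for i, s in enumerate(self.samples):
                c = self.counts[i, flat]
                if c.sum():
                    col[s] = {_BASE_ORDER[b]: int(c[b]) for b in range(4) if c[b]}
            yield PileupColumn(ref_id=ref_id, pos=pos, counts=col)


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASE_ORDER):
    _CODE[ord(_b)] = _i


def build_pileup(
    alignments: Mapping[str, str | os.PathLike | Iterable[AlignedRead]],
    reference: Mapping[str, str],
) -> Pileup:
    """Build per-sample base-count pileups from SAM records.

    Only primary, mapped, proper-pair records contribute; everything else is
    skipped and counted. Overlapping mate bases each count toward depth.
    N bases are dropped. The genomewide mean coverage per sample is total
    aligned bases divided by total reference length.
    """
    samples = list(alignments)
    ref_names = list(reference)
    ref_lengths = {n: len(s) for n, s in reference.items()}
    offsets, off = {}, 0
    for n in ref_names:
        offsets[n] = off
        off += ref_lengths[n]
    total_len = off

    counts = np.zeros((len(samples), total_len, 4), dtype=np.int32)
    aligned_bases = np.zeros(len(samples), dtype=np.int64)
    skipped: dict[str, int] = {}

    for si, sample in enumerate(samples):
        src = alignments[sample]
        records = read_sam(src) if isinstance(src, (str, os.PathLike)) else src
        pos_chunks: list[np.ndarray] = []
        code_chunks: list[np.ndarray] = []
        n_skip = 0
        for rec in records:
            if rec.is_unmapped or not rec.is_proper_pair or not rec.is_primary:
                n_skip += 1
                continue
            if rec.ref_id not in offsets:
                raise ValueError(f"read {rec.qname} aligned to unknown reference {rec.ref_id!r}")
            base_off = offsets[rec.ref_id]
            if rec.cigar.endswith("M") and rec.cigar[:-1].isdigit():
                # fast path: single full-length match
                n = int(rec.cigar[:-1])
                if rec.pos + n > ref_lengths[rec.ref_id]:
                    raise ValueError(
                        f"read {rec.qname} extends beyond the end of reference {rec.ref_id!r}"
                    )
                codes = _CODE[np.frombuffer(rec.seq.encode(), dtype=np.uint8)[:n]]
                pos = base_off + rec.pos + np.arange(n)
            else:
                pairs = list(rec.aligned_pairs())
                if pairs and pairs[-1][0] >= ref_lengths[rec.ref_id]:
                    raise ValueError(
                        f"read {rec.qname} extends beyond the end of reference {rec.ref_id!r}"
                    )
                pos = base_off + np.array([p for p, _ in pairs], dtype=np.int64)
                codes = _CODE[np.frombuffer("".join(b for _, b in pairs).encode(), np.uint8)]
            keep = codes >= 0  # drop N
            pos_chunks.append(pos[keep])
            code_chunks.append(codes[keep])
        if pos_chunks:
            allpos = np.concatenate(pos_chunks)
            allcodes = np.concatenate(code_chunks).astype(np.int64)
            np.add.at(counts[si].reshape(-1), allpos * 4 + allcodes, 1)
            aligned_bases[si] = allpos.size
        if n_skip:
            skipped[sample] = n_skip

    means = aligned_bases / max(total_len, 1)
    if np.any(aligned_bases == 0):
        empty = [s for s, b in zip(samples, aligned_bases) if b == 0]
        warnings.warn(f"no usable alignments for sample(s): {', '.join(empty)}", stacklevel=2)
    stats = CoverageStats(
        samples=samples,
        reference_length=total_len,
        genomewide_mean=means,
        skipped_records=skipped,
    )
    return Pileup(
        samples=samples,
        ref_names=ref_names,
        ref_lengths=ref_lengths,
        offsets=offsets,
        counts=counts,
        stats=stats,
    )


@dataclass
class SnpCalls:
    flat_positions: np.ndarray  # concatenated-axis coordinates
    alleles: np.ndarray  # (n_snps, 2) base codes, support-ordered
    triallelic: np.ndarray  # bool per SNP

    def __len__(self) -> int:
        return self.flat_positions.size


def call_snps(pileup: Pileup, min_alt_reads: int = 2) -> SnpCalls:
    """Reference-free raw SNP discovery.

    A position is a raw SNP when at least two distinct bases each have
    >= `min_alt_reads` supporting reads summed across samples. The two
    best-supported bases become the alleles (reported in base order);
    support ties break by base order A<C<G<T. Positions where a third base
    also clears the threshold are marked triallelic.
    """
    total = pileup.counts.sum(axis=0)  # (L, 4)
    qualifying = total >= min_alt_reads
    is_snp = qualifying.sum(axis=1) >= 2
    flat = np.flatnonzero(is_snp)
    # per-base sort key: higher support first, ties to the lower base code
    key = total[flat].astype(np.int64) * 4 - np.arange(4)
    order = np.argsort(-key, axis=1, kind="stable")
    alleles = order[:, :2].astype(np.int8)
    alleles.sort(axis=1)  # report allele pair in base order
    triallelic = qualifying[flat].sum(axis=1) >= 3
    return SnpCalls(flat_positions=flat, alleles=alleles, triallelic=triallelic)


@dataclass
class GenotypeMatrix:
    """Samples x SNP positions of fixed diploid calls.

    `calls` holds call codes (0-3 homozygote base, 4-9 IUPAC heterozygote,
    -1 missing); `depth` the per-cell read depth the call was made from.
    """

    samples: list[str]
    positions: list[tuple[str, int]]
    calls: np.ndarray  # (n_samples, n_sites) int8
    depth: np.ndarray  # (n_samples, n_sites) int32

    @property
    def site_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def to_strings(self) -> dict[str, str]:
        lut = np.array(list(_CALL_CHAR + "N"))
        idx = self.calls.copy()
        idx[idx == MISSING] = len(_CALL_CHAR)
        return {s: "".join(lut[idx[i]]) for i, s in enumerate(self.samples)}

    def take_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            positions=[self.positions[i] for i in keep],
            calls=self.calls[:, keep].copy(),
            depth=self.depth[:, keep].copy(),
        )


def genotype_at_snps(
    pileup: Pileup, snps: SnpCalls, min_het_reads: int = 1
) -> GenotypeMatrix:
    """Fixed genotype calls at called SNP positions.

    Per sample and site: no reads -> missing; one observed base ->
    homozygote; two observed bases -> IUPAC heterozygote (each allele
    needing >= `min_het_reads` reads, otherwise the better-supported base
    is called homozygous, ties breaking by base order); more than two
    observed bases -> missing.
    """
    flat = snps.flat_positions
    sub = pileup.counts[:, flat, :]  # (n_samples, n_snps, 4)
    n_obs = (sub > 0).sum(axis=2)
    depth = sub.sum(axis=2)
    calls = np.full(sub.shape[:2], MISSING, dtype=np.int8)

    # homozygote: exactly one observed base
    hom = n_obs == 1
    calls[hom] = np.argmax(sub[hom] > 0, axis=1).astype(np.int8)

    # heterozygote: exactly two observed bases
    two = n_obs == 2
    if two.any():
        idx = np.argsort(sub[two] > 0, axis=1, kind="stable")
        lo = idx[:, -2].astype(np.int8)
        hi = idx[:, -1].astype(np.int8)
        a = np.minimum(lo, hi)
        b = np.maximum(lo, hi)
        pair_lut = np.full((4, 4), MISSING, dtype=np.int8)
        for (i, j), code in _PAIR_CODE.items():
            pair_lut[i, j] = code
        het_calls = pair_lut[a, b]
        if min_het_reads > 1:
            counts_two = sub[two]
            n_a = counts_two[np.arange(a.size), a]
            n_b = counts_two[np.arange(b.size), b]
            weak = (n_a < min_het_reads) | (n_b < min_het_reads)
            major = np.where(n_a >= n_b, a, b)  # tie -> lower base code
            het_calls = np.where(weak, major, het_calls)
        calls[two] = het_calls

    positions = [pileup.position_of(int(f)) for f in flat]
    return GenotypeMatrix(
        samples=list(pileup.samples),
        positions=positions,
        calls=calls,
        depth=depth.astype(np.int32),
    )


def filter_matrix(
    matrix: GenotypeMatrix,
    stats: CoverageStats,
    depth_multiplier: float = 2.5,
    max_missing: float = 0.5,
) -> GenotypeMatrix:
    """High-coverage exclusion plus missing-data threshold.

    A cell whose depth exceeds `depth_multiplier` x that sample's own
    genomewide mean coverage is set to missing (likely collapsed repeat);
    sites whose missing fraction then exceeds `max_missing` (strictly) are
    discarded. The operation is idempotent. The two presets used in
    practice are max_missing=0.5 (phylogenetic set) and 0.1 (structure
    set).
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be within [0, 1]")
    means = np.array([stats.mean_of(s) for s in matrix.samples])
    out = GenotypeMatrix(
        samples=list(matrix.samples),
        positions=list(matrix.positions),
        calls=matrix.calls.copy(),
        depth=matrix.depth.copy(),
    )
    too_deep = out.depth > depth_multiplier * means[:, None]
    out.calls[too_deep] = MISSING
    keep = out.site_missing_fraction <= max_missing
    return out.take_sites(keep)


def flag_duplicated_regions(
    snps: SnpCalls,
    pileup: Pileup,
    depth_cut: int = 5,
    sample_frac: float = 0.5,
) -> np.ndarray:
    """Flag SNPs whose depth exceeds `depth_cut` in at least `sample_frac`
    of samples — the signature of regions duplicated relative to the
    mapping reference, which collapse into spuriously deep columns.

    Returns a boolean array over the SNP list (True = flagged).
    """
    depth = pileup.depth[:, snps.flat_positions]
    frac_deep = (depth > depth_cut).mean(axis=0)
    return frac_deep >= sample_frac


def resample_to_equal_bases(
    alignments: Mapping[str, Sequence[AlignedRead]],
    exempt: Sequence[str] = (),
    seed: int | None = None,
) -> dict[str, list[AlignedRead]]:
    """Randomly subsample read pairs so every sample carries the same
    number of aligned bases.

    The target is the lowest per-sample total among non-exempt samples.
    Pairs (grouped by query name) are drawn without replacement until
    adding the next pair would exceed the target; exempt samples pass
    through untouched.
    """
    for s in exempt:
        if s not in alignments:
            raise ValueError(f"exempt sample {s!r} not present")
    rng = np.random.default_rng(seed)

    def usable(rec: AlignedRead) -> bool:
        return not rec.is_unmapped and rec.is_proper_pair and rec.is_primary

    fragments: dict[str, list[tuple[str, list[AlignedRead], int]]] = {}
    totals: dict[str, int] = {}
    for sample, recs in alignments.items():
        groups: dict[str, list[AlignedRead]] = {}
        for rec in recs:
            if usable(rec):
                groups.setdefault(rec.qname, []).append(rec)
        frags = [
            (qname, members, sum(r.aligned_length() for r in members))
            for qname, members in groups.items()
        ]
        fragments[sample] = frags
        totals[sample] = sum(f[2] for f in frags)

    nonexempt = [s for s in alignments if s not in exempt]
    if len(alignments) < 2:
        raise ValueError("resampling needs at least two samples")
    target = min(totals[s] for s in nonexempt)

    out: dict[str, list[AlignedRead]] = {}
    for sample, recs in alignments.items():
        if sample in exempt:
            out[sample] = list(recs)
            continue
        frags = fragments[sample]
        order = rng.permutation(len(frags))
        kept: list[AlignedRead] = []
        acc = 0
        for i in order:
            qname, members, nbases = frags[i]
            if acc + nbases > target:
                break
            kept.extend(members)
            acc += nbases
        out[sample] = kept
    return out


def export_iupac_alignment(
    matrix: GenotypeMatrix, path: str | os.PathLike | None = None, fmt: str = "fasta"
) -> str:
    """Serialize the matrix as one IUPAC-coded sequence per sample
    (missing -> N), in FASTA or relaxed PHYLIP."""
    seqs = matrix.to_strings()
    if fmt == "fasta":
        text = "".join(f">{name}\n{seq}\n" for name, seq in seqs.items())
    elif fmt == "phylip":
        lines = [f" {len(seqs)} {matrix.n_sites}"]
        lines += [f"{name}  {seq}" for name, seq in seqs.items()]
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def export_vcf(matrix: GenotypeMatrix, path: str | os.PathLike | None = None) -> str:
    """Write the matrix as VCF 4.2 with GT:DP fields ("./." for missing).

    REF is the lexicographically first base observed at the site (the
    matrix tracks no external reference allele); ALT lists the remaining
    observed bases in base order.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for ref_id in dict.fromkeys(r for r, _ in matrix.positions):
        lines.append(f"##contig=<ID={ref_id}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples)
    )
    for j, (ref_id, pos) in enumerate(matrix.positions):
        observed: set[str] = set()
        for i in range(len(matrix.samples)):
            c = matrix.calls[i, j]
            if c == MISSING:
                continue
            if c < 4:
                observed.add(_BASE_ORDER[c])
            else:
                observed |= set(HET_SETS[_CALL_CHAR[c]])
        bases = sorted(observed)
        if not bases:
            bases = ["A"]
        ref = bases[0]
        alts = bases[1:] or ["."]
        index = {b: k for k, b in enumerate(bases)}
        gts = []
        for i in range(len(matrix.samples)):
            c = matrix.calls[i, j]
            if c == MISSING:
                gts.append("./.:" + str(int(matrix.depth[i, j])))
                continue
            if c < 4:
                k = index[_BASE_ORDER[c]]
                gt = f"{k}/{k}"
            else:
                a, b = sorted(HET_SETS[_CALL_CHAR[c]])
                gt = f"{index[a]}/{index[b]}"
            gts.append(f"{gt}:{int(matrix.depth[i, j])}")
        lines.append(
            f"{ref_id}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT:DP\t" + "\t".join(gts)
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF (as written by `export_vcf`) back into a GenotypeMatrix."""
    samples: list[str] = []
    positions: list[tuple[str, int]] = []
    call_rows: list[list[int]] = []
    depth_rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            chrom, pos, ref, alt = f[0], int(f[1]) - 1, f[3], f[4]
            alleles = [ref] + ([] if alt == "." else alt.split(","))
            fmt_keys = f[8].split(":")
            gt_i = fmt_keys.index("GT")
            dp_i = fmt_keys.index("DP") if "DP" in fmt_keys else None
            calls, depths = [], []
            for cell in f[9:]:
                parts = cell.split(":")
                gt = parts[gt_i].replace("|", "/")
                depths.append(int(parts[dp_i]) if dp_i is not None and parts[dp_i] != "." else 0)
                if "." in gt:
                    calls.append(int(MISSING))
                    continue
                a, b = (alleles[int(x)] for x in gt.split("/"))
                if a == b:
                    calls.append(int(char_to_call(a)))
                else:
                    calls.append(int(het_code(a, b)))
            positions.append((chrom, pos))
            call_rows.append(calls)
            depth_rows.append(depths)
    return GenotypeMatrix(
        samples=samples,
        positions=positions,
        calls=np.array(call_rows, dtype=np.int8).T.copy()
        if call_rows
        else np.zeros((len(samples), 0), np.int8),
        depth=np.array(depth_rows, dtype=np.int32).T.copy()
        if depth_rows
        else np.zeros((len(samples), 0), np.int32),
    )


def quality_filter_reads(
    reads: Iterable[tuple[str, str, str]],
    min_quality: int = 20,
    max_low_fraction: float = 0.2,
) -> list[tuple[str, str, str]]:
    """Optional FASTQ pre-pass mirroring standard read QC: drop reads with
    ambiguous bases or with more than `max_low_fraction` of bases below
    `min_quality`, then trim below-threshold bases from the 3' end."""
    out = []
    for name, seq, qual in reads:
        if any(b not in "ACGT" for b in seq):
            continue
        q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33
        if (q < min_quality).mean() > max_low_fraction:
            continue
        end = len(seq)
        while end > 0 and q[end - 1] < min_quality:
            end -= 1
        if end == 0:
            continue
        out.append((name, seq[:end], qual[:end]))
    return out
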