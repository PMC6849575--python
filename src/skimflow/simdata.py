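"""Synthetic genome-skimming data with known truth.

Generates the statistical structure the downstream analyses assume: gene
trees drawn under the multispecies coalescent on a (typically 4-clade)
species tree, optional discrete introgression pulses, laterally transferred
gene copies from a distant donor, diploid genomes, and low-coverage
paired-end reads with sequencing error. Every stage emits machine-readable
truth so parameter-recovery tests can compare pipeline output against the
generating process.

Time is measured in coalescent units (2N generations of the reference
population); mutation rates are per site per coalescent unit. A fixed seed
yields byte-identical FASTQ/SAM/truth outputs.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import msprime
import numpy as np

from .io import (
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    FLAG_SECOND,
    FLAG_UNMAPPED,
    AlignedRead,
    write_fasta,
    write_fastq,
    write_sam,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMPLEMENT[arr][::-1].tobytes().decode()


@dataclass(frozen=True)
class IntrogressionEvent:
    """A discrete gene-flow pulse: at `time` (coalescent units, backwards
    from the present) each lineage sampled in `recipient` derives from
    `donor` with probability `proportion`."""

    donor: str
    recipient: str
    time: float
    proportion: float


@dataclass(frozen=True)
class LgtEvent:
    """A laterally transferred gene copy.

    The vertical homolog occupies ``[region_start, region_start+region_length)``
    on the simulated genome; the donor copy diverges from it by
    ``donor_divergence`` substitutions per site and is inserted (as an extra
    copy, appended after the core genome) into the genomes of
    ``recipients`` only. ``inserted_span`` restricts the insertion to a
    sub-interval of the gene, producing a truncated (pseudogenized) copy.
    """

    gene_id: str
    donor_divergence: float
    recipients: tuple[str, ...]
    region_length: int
    region_start: int | None = None
    inserted_span: tuple[int, int] | None = None


@dataclass
class SimulationConfig:
    species_tree: str = "(((P1:1.0,P2:1.0):1.0,P3:2.0):1.0,O:3.0);"
    pop_size: float | Mapping[str, float] = 1.0  # relative size per branch
    introgression_events: Sequence[IntrogressionEvent] = field(default_factory=list)
    lgt_events: Sequence[LgtEvent] = field(default_factory=list)
    n_loci: int = 100
    locus_length: int = 1000
    mutation_rate: float = 0.01  # per site per coalescent unit
    samples_per_tip: int = 1
    coverage: float = 2.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    reference_divergence: float = 0.05
    quality_mode: str = "flat30"  # or "tail15": low-quality 3' tail
    seed: int = 1

    def validate(self) -> None:
        for ev in self.introgression_events:
            if not 0.0 <= ev.proportion <= 1.0:
                raise ValueError(f"introgression proportion {ev.proportion} outside [0,1]")
            if ev.time < 0:
                raise ValueError("introgression event time must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length > self.locus_length:
            raise ValueError("read_length must not exceed locus_length")
        if self.n_loci < 0 or self.locus_length <= 0:
            raise ValueError("n_loci and locus_length must be non-negative / positive")
        if not 0.0 <= self.reference_divergence < 1.0:
            raise ValueError("reference_divergence outside [0,1)")


@dataclass
class SiteTruth:
    pos: int  # position on the concatenated genome (0-based)
    ancestral: str
    derived: str
    genotypes: np.ndarray  # (n_samples, 2) of 0/1 (0 = ancestral)


@dataclass
class SimulationTruth:
    sample_names: list[str]
    tip_of_sample: dict[str, str]
    n_loci: int
    locus_length: int
    gene_trees: list[str]
    sites: list[SiteTruth]
    introgression_records: list[dict]
    lgt_records: list[dict] = field(default_factory=list)

    @property
    def genome_length(self) -> int:
        return self.n_loci * self.locus_length

    def genotype_bases(self) -> dict[str, np.ndarray]:
        """Per sample: (n_sites, 2) array of true diploid bases (chars)."""
        out = {}
        for i, name in enumerate(self.sample_names):
            rows = []
            for s in self.sites:
                pair = [s.ancestral if g == 0 else s.derived for g in s.genotypes[i]]
                rows.append(pair)
            out[name] = np.array(rows)
        return out

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "sample_names": self.sample_names,
            "tip_of_sample": self.tip_of_sample,
            "n_loci": self.n_loci,
            "locus_length": self.locus_length,
            "gene_trees": self.gene_trees,
            "sites": [
                {
                    "pos": s.pos,
                    "ancestral": s.ancestral,
                    "derived": s.derived,
                    "genotypes": s.genotypes.tolist(),
                }
                for s in self.sites
            ],
            "introgression_records": self.introgression_records,
            "lgt_records": self.lgt_records,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _parse_species_tree(newick: str) -> tuple[dendropy.Tree, dict[str, float], float]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    ages: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[id(node)] = 0.0
        else:
            child_ages = [
                ages[id(c)] + (c.edge.length if c.edge.length is not None else 0.0)
                for c in node.child_nodes()
            ]
            if max(child_ages) - min(child_ages) > 1e-6:
                raise ValueError("species tree must be ultrametric in coalescent units")
            ages[id(node)] = child_ages[0]
    root_age = ages[id(tree.seed_node)]
    named = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.pop_name = node.taxon.label
        else:
            leaves = sorted(l.taxon.label for l in node.leaf_iter())
            node.pop_name = "anc_" + "_".join(leaves)
        named[node.pop_name] = ages[id(node)]
    return tree, named, root_age


def _build_demography(config: SimulationConfig) -> tuple[msprime.Demography, list[str], float]:
    tree, node_ages, root_age = _parse_species_tree(config.species_tree)
    for ev in config.introgression_events:
        if ev.time >= root_age:
            raise ValueError(
                f"introgression event at time {ev.time} is older than the species-tree root ({root_age})"
            )
        for name in (ev.donor, ev.recipient):
            if name not in node_ages:
                raise ValueError(f"unknown population {name!r} in introgression event")

    def rel_size(name: str) -> float:
        if isinstance(config.pop_size, Mapping):
            return float(config.pop_size.get(name, 1.0))
        return float(config.pop_size)

    demog = msprime.Demography()
    for node in tree.postorder_node_iter():
        # initial_size 0.5 * rel makes one time unit = one coalescent unit
        demog.add_population(name=node.pop_name, initial_size=0.5 * rel_size(node.pop_name))
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    internals.sort(key=lambda n: node_ages[n.pop_name])
    for node in internals:
        demog.add_population_split(
            time=node_ages[node.pop_name],
            derived=[c.pop_name for c in node.child_nodes()],
            ancestral=node.pop_name,
        )
    for ev in config.introgression_events:
        # backwards in time: recipient lineages trace into the donor
        demog.add_mass_migration(
            time=ev.time, source=ev.recipient, dest=ev.donor, proportion=ev.proportion
        )
    demog.sort_events()
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    return demog, tips, root_age


def _sample_names(tips: Sequence[str], per_tip: int) -> list[str]:
    if per_tip == 1:
        return list(tips)
    return [f"{t}.{i + 1}" for t in tips for i in range(per_tip)]


def simulate_genealogies(config: SimulationConfig) -> SimulationTruth:
    """Sample per-locus gene trees and segregating sites under the
    multispecies coalescent with optional introgression pulses.

    Mutations follow an infinite-sites regime within each locus: sites hit
    by more than one mutation (rare at the default rate) are dropped so
    every retained segregating site traces to exactly one gene-tree branch.
    """
    config.validate()
    demog, tips, _ = _build_demography(config)
    names = _sample_names(tips, config.samples_per_tip)
    tip_of = {}
    for t in tips:
        for n in names:
            if n == t or n.startswith(t + "."):
                tip_of[n] = t

    truth = SimulationTruth(
        sample_names=names,
        tip_of_sample=tip_of,
        n_loci=config.n_loci,
        locus_length=config.locus_length,
        gene_trees=[],
        sites=[],
        introgression_records=[],
    )
    if config.n_loci == 0:
        return truth

    ss = np.random.SeedSequence(config.seed)
    anc_ss, mut_ss, _, _ = ss.spawn(4)
    anc_seed = int(anc_ss.generate_state(1, np.uint32)[0] % (2**31 - 1)) + 1
    mut_seeds = mut_ss.generate_state(config.n_loci, np.uint32) % (2**31 - 1) + 1

    sample_sets = [
        msprime.SampleSet(config.samples_per_tip, population=t, ploidy=2) for t in tips
    ]
    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=demog,
        sequence_length=config.locus_length,
        ploidy=2,
        num_replicates=config.n_loci,
        random_seed=anc_seed,
        record_migrations=bool(config.introgression_events),
    )
    pulse_migrants = {i: 0 for i in range(len(config.introgression_events))}
    node_label_cache: dict[int, str] | None = None
    for locus, ts in enumerate(reps):
        if node_label_cache is None:
            node_label_cache = {}
            for ind_idx, ind in enumerate(ts.individuals()):
                for k, node in enumerate(ind.nodes):
                    node_label_cache[node] = f"{names[ind_idx]}_{'ab'[k]}"
        truth.gene_trees.append(ts.first().newick(node_labels=node_label_cache))
        if config.introgression_events:
            for mig in ts.migrations():
                for i, ev in enumerate(config.introgression_events):
                    if abs(mig.time - ev.time) < 1e-9:
                        pulse_migrants[i] += 1
        mts = msprime.sim_mutations(
            ts,
            rate=config.mutation_rate,
            random_seed=int(mut_seeds[locus]),
            model=msprime.JC69(),
            discrete_genome=True,
        )
        offset = locus * config.locus_length
        for var in mts.variants():
            site = var.site
            if len(site.mutations) != 1 or len(var.alleles) != 2:
                continue  # infinite-sites bookkeeping: one mutation per site
            geno = np.asarray(var.genotypes, dtype=np.int8).reshape(-1, 2)
            truth.sites.append(
                SiteTruth(
                    pos=offset + int(site.position),
                    ancestral=var.alleles[0],
                    derived=var.alleles[1],
                    genotypes=geno,
                )
            )
    truth.introgression_records = [
        {
            "donor": ev.donor,
            "recipient": ev.recipient,
            "time": ev.time,
            "proportion": ev.proportion,
            "migrant_lineages": pulse_migrants[i],
        }
        for i, ev in enumerate(config.introgression_events)
    ]
    return truth


@dataclass
class Genomes:
    reference: str
    haplotypes: dict[str, tuple[str, str]]
    # per sample: appended extra-copy segments (gene_id, offset_in_haplotype, length)
    appended: dict[str, list[tuple[str, int, int]]]

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta({"ref": self.reference}, os.path.join(outdir, "reference.fasta"))
        haps = {}
        for sample, (a, b) in self.haplotypes.items():
            haps[f"{sample}_hapA"] = a
            haps[f"{sample}_hapB"] = b
        write_fasta(haps, os.path.join(outdir, "haplotypes.fasta"))


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases independently at `rate`, never back to the same base."""
    out = arr.copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        codes = _CODE[out[mask]]
        shift = rng.integers(1, 4, size=n)
        out[mask] = _BASES[(codes + shift) % 4]
    return out


def realize_genomes(truth: SimulationTruth, config: SimulationConfig) -> Genomes:
    """Turn genealogical truth into concrete sequences.

    Produces one reference haplotype (the ancestral genome plus private
    divergence, emulating a distantly related mapping target) and two
    haplotypes per diploid sample. LGT events append a donor-derived gene
    copy to the recipient genomes only.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    _, _, gen_ss, _ = ss.spawn(4)
    rng = np.random.default_rng(gen_ss)
    glen = truth.genome_length

    ancestral = _BASES[rng.integers(0, 4, size=glen)]
    site_pos = np.array([s.pos for s in truth.sites], dtype=np.int64)
    for s in truth.sites:
        ancestral[s.pos] = ord(s.ancestral)

    haplotypes: dict[str, list[np.ndarray]] = {}
    for i, name in enumerate(truth.sample_names):
        haps = [ancestral.copy(), ancestral.copy()]
        for s in truth.sites:
            for k in range(2):
                if s.genotypes[i, k] == 1:
                    haps[k][s.pos] = ord(s.derived)
        haplotypes[name] = haps

    # reference private divergence, outside segregating sites so the truth
    # site table remains the complete catalogue of polymorphism
    reference = ancestral.copy()
    if config.reference_divergence > 0 and glen > 0:
        keep = np.ones(glen, dtype=bool)
        keep[site_pos] = False
        idx = np.flatnonzero(keep)
        sub = idx[rng.random(idx.size) < config.reference_divergence]
        codes = _CODE[reference[sub]]
        reference[sub] = _BASES[(codes + rng.integers(1, 4, size=sub.size)) % 4]

    # lateral gene transfer: donor copy appended to recipient genomes
    appended: dict[str, list[tuple[str, int, int]]] = {n: [] for n in truth.sample_names}
    regions: list[tuple[int, int]] = []
    cursor = 0
    truth.lgt_records = []
    for ev in config.lgt_events:
        start = ev.region_start if ev.region_start is not None else cursor
        end = start + ev.region_length
        cursor = max(cursor, end)
        if end > glen:
            raise ValueError(f"LGT region for {ev.gene_id} extends past the genome end")
        for s0, e0 in regions:
            if start < e0 and s0 < end:
                raise ValueError(f"overlapping LGT regions ({ev.gene_id})")
        regions.append((start, end))
        donor = _mutate(ancestral[start:end], ev.donor_divergence, rng)
        span = ev.inserted_span or (0, ev.region_length)
        inserted = donor[span[0] : span[1]]
        for rec in ev.recipients:
            matches = [n for n in truth.sample_names if truth.tip_of_sample[n] == rec or n == rec]
            if not matches:
                raise ValueError(f"LGT recipient {rec!r} matches no sample or tip")
            for name in matches:
                for k in range(2):
                    off = len(haplotypes[name][k])
                    haplotypes[name][k] = np.concatenate([haplotypes[name][k], inserted])
                    if k == 0:
                        appended[name].append((ev.gene_id, off, inserted.size))
        truth.lgt_records.append(
            {
                "gene_id": ev.gene_id,
                "recipients": list(ev.recipients),
                "region_start": start,
                "region_end": end,
                "inserted_span": list(span),
                "donor_divergence": ev.donor_divergence,
                "donor_seq": donor.tobytes().decode(),
                "inserted_seq": inserted.tobytes().decode(),
            }
        )

    return Genomes(
        reference=reference.tobytes().decode(),
        haplotypes={
            n: (h[0].tobytes().decode(), h[1].tobytes().decode()) for n, h in haplotypes.items()
        },
        appended=appended,
    )


@dataclass
class ReadPair:
    qname: str
    sample: str
    segment: str  # "ref" for the core genome, else the LGT gene id
    start: int  # fragment start within the segment
    insert: int
    seq1: str  # as sequenced (forward)
    seq2: str  # as sequenced (reverse-complement orientation)


@dataclass
class ReadSet:
    pairs: dict[str, list[ReadPair]]  # per sample
    read_length: int
    quality_mode: str = "flat30"

    def _qual(self) -> str:
        n = self.read_length
        if self.quality_mode == "tail15":
            tail = max(1, n // 10)
            return chr(30 + 33) * (n - tail) + chr(15 + 33) * tail
        return chr(30 + 33) * n

    def fastq_records(self, sample: str) -> tuple[list, list]:
        q = self._qual()
        r1 = [(p.qname + "/1", p.seq1, q) for p in self.pairs[sample]]
        r2 = [(p.qname + "/2", p.seq2, q) for p in self.pairs[sample]]
        return r1, r2

    def sam_records(self, sample: str) -> list[AlignedRead]:
        """True alignments. Reads from appended LGT copies have no position
        on the mapping reference and are emitted unmapped."""
        out = []
        rl = self.read_length
        for p in self.pairs[sample]:
            if p.segment == "ref":
                f1 = FLAG_PAIRED | FLAG_PROPER | FLAG_MATE_REVERSE | FLAG_FIRST
                f2 = FLAG_PAIRED | FLAG_PROPER | FLAG_REVERSE | FLAG_SECOND
                out.append(AlignedRead(p.qname, f1, "ref", p.start, f"{rl}M", p.seq1))
                out.append(
                    AlignedRead(
                        p.qname, f2, "ref", p.start + p.insert - rl, f"{rl}M", revcomp(p.seq2)
                    )
                )
            else:
                f1 = FLAG_PAIRED | FLAG_UNMAPPED | FLAG_MATE_UNMAPPED | FLAG_FIRST
                f2 = FLAG_PAIRED | FLAG_UNMAPPED | FLAG_MATE_UNMAPPED | FLAG_SECOND
                out.append(AlignedRead(p.qname, f1, "*", -1, "*", p.seq1))
                out.append(AlignedRead(p.qname, f2, "*", -1, "*", p.seq2))
        return out

    def write(self, outdir: str | os.PathLike, reference_length: int) -> None:
        os.makedirs(outdir, exist_ok=True)
        for sample in self.pairs:
            r1, r2 = self.fastq_records(sample)
            write_fastq(r1, os.path.join(outdir, f"{sample}_R1.fastq"))
            write_fastq(r2, os.path.join(outdir, f"{sample}_R2.fastq"))
            write_sam(
                self.sam_records(sample),
                {"ref": reference_length},
                os.path.join(outdir, f"{sample}.sam"),
                qual_char=chr(30 + 33),
            )


def simulate_reads(genomes: Genomes, config: SimulationConfig) -> ReadSet:
    """Draw error-prone paired-end reads to the configured mean depth.

    Fragment starts are uniform within each genome segment (core genome and
    any appended LGT copies, in proportion to length); insert sizes are
    normal, truncated below at the read length.
    """
    config.validate()
    if config.insert_mean < config.read_length:
        raise ValueError("insert_mean must be >= read_length")
    ss = np.random.SeedSequence(config.seed)
    _, _, _, read_ss = ss.spawn(4)
    rng = np.random.default_rng(read_ss)
    rl = config.read_length
    glen = len(genomes.reference)

    pairs: dict[str, list[ReadPair]] = {}
    for sample, haps in genomes.haplotypes.items():
        segments = [("ref", 0, glen)] + [
            (gid, off, ln) for gid, off, ln in genomes.appended.get(sample, [])
        ]
        plist: list[ReadPair] = []
        serial = 0
        for k, hap in enumerate(haps):
            hap_arr = np.frombuffer(hap.encode(), dtype=np.uint8)
            n_pairs_hap = int(round(config.coverage * len(hap) / (2 * rl) / 2))
            seg_lens = np.array([s[2] for s in segments], dtype=float)
            n_per_seg = rng.multinomial(n_pairs_hap, seg_lens / seg_lens.sum())
            for (seg_id, seg_off, seg_len), n_seg in zip(segments, n_per_seg):
                if n_seg == 0 or seg_len < rl:
                    continue
                inserts = np.clip(
                    np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_seg)),
                    rl,
                    seg_len,
                ).astype(np.int64)
                starts = (rng.random(n_seg) * (seg_len - inserts + 1)).astype(np.int64)
                idx1 = (seg_off + starts)[:, None] + np.arange(rl)[None, :]
                idx2 = (seg_off + starts + inserts - rl)[:, None] + np.arange(rl)[None, :]
                m1 = hap_arr[idx1]
                m2f = hap_arr[idx2]
                if config.error_rate > 0:
                    m1 = _mutate_matrix(m1, config.error_rate, rng)
                    m2f = _mutate_matrix(m2f, config.error_rate, rng)
                for j in range(n_seg):
                    seq1 = m1[j].tobytes().decode()
                    seq2 = _COMPLEMENT[m2f[j]][::-1].tobytes().decode()
                    plist.append(
                        ReadPair(
                            qname=f"{sample}:{serial}",
                            sample=sample,
                            segment=seg_id,
                            start=int(starts[j]),
                            insert=int(inserts[j]),
                            seq1=seq1,
                            seq2=seq2,
                        )
                    )
                    serial += 1
        pairs[sample] = plist
    return ReadSet(pairs=pairs, read_length=rl, quality_mode=config.quality_mode)


def _mutate_matrix(m: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = m.copy()
    mask = rng.random(m.shape) < rate
    n = int(mask.sum())
    if n:
        codes = _CODE[out[mask]]
        out[mask] = _BASES[(codes + rng.integers(1, 4, size=n)) % 4]
    return out


def truth_matrix(truth: SimulationTruth):
    """True genotypes as a GenotypeMatrix (depth set to a nominal 100x),
    bypassing reads entirely — the oracle endpoint for recovery tests."""
    from .genotyping import GenotypeMatrix, char_to_call, het_code

    n = len(truth.sample_names)
    calls = np.zeros((n, len(truth.sites)), dtype=np.int8)
    for j, s in enumerate(truth.sites):
        for i in range(n):
            a = s.ancestral if s.genotypes[i, 0] == 0 else s.derived
            b = s.ancestral if s.genotypes[i, 1] == 0 else s.derived
            calls[i, j] = char_to_call(a) if a == b else het_code(a, b)
    return GenotypeMatrix(
        samples=list(truth.sample_names),
        positions=[("ref", s.pos) for s in truth.sites],
        calls=calls,
        depth=np.full((n, len(truth.sites)), 100, dtype=np.int32),
    )


def simulate(config: SimulationConfig) -> tuple[SimulationTruth, Genomes, ReadSet]:
    """Run all three stages: genealogies -> genomes -> reads."""
    truth = simulate_genealogies(config)
    genomes = realize_genomes(truth, config)
    reads = simulate_reads(genomes, config)
    return truth, genomes, reads
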