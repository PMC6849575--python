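"""Genotyping stack: pileups, SNP calling, filters, resampling, export."""

import numpy as np
import pytest
from scipy.stats import binomtest

from skimflow import genotyping as gt
from skimflow import simdata as sim
from skimflow.io import AlignedRead

from conftest import make_pileup

PROPER = 0x1 | 0x2 | 0x40  # paired, proper, first-in-pair


def _read(qname, pos, seq, flag=PROPER, ref="ref"):
    return AlignedRead(qname=qname, flag=flag, ref_id=ref, pos=pos, cigar=f"{len(seq)}M", seq=seq)


class TestBuildPileup:
    def test_genomewide_mean_is_aligned_bases_over_reference_length(self):
        ref = {"ref": "A" * 1000}
        reads = [_read("r1", 0, "A" * 100), _read("r2", 500, "A" * 100)]
        pileup = gt.build_pileup({"S1": reads}, ref)
        assert pileup.stats.mean_of("S1") == pytest.approx(0.2)

    def test_overlapping_mates_each_count_toward_depth(self):
        ref = {"ref": "A" * 300}
        reads = [_read("p1", 0, "A" * 100), _read("p1", 50, "A" * 100, flag=0x1 | 0x2 | 0x80)]
        pileup = gt.build_pileup({"S1": reads}, ref)
        depth = pileup.depth[0]
        assert depth[75] == 2 and depth[25] == 1 and depth[125] == 1

    def test_empty_alignments_warn_and_give_zero_mean(self):
        with pytest.warns(UserWarning, match="no usable alignments"):
            pileup = gt.build_pileup({"S1": []}, {"ref": "ACGT" * 100})
        assert pileup.stats.mean_of("S1") == 0.0

    def test_read_past_reference_end_raises_with_name(self):
        with pytest.raises(ValueError, match="r_bad"):
            gt.build_pileup({"S1": [_read("r_bad", 950, "A" * 100)]}, {"ref": "A" * 1000})

    def test_improper_and_secondary_records_skipped(self):
        ref = {"ref": "A" * 200}
        reads = [
            _read("ok", 0, "A" * 100),
            _read("unpaired", 0, "A" * 100, flag=0x1 | 0x40),  # not proper pair
            _read("secondary", 0, "A" * 100, flag=PROPER | 0x100),
            _read("dup", 0, "A" * 100, flag=PROPER | 0x400),
        ]
        pileup = gt.build_pileup({"S1": reads}, ref)
        assert pileup.stats.skipped_records["S1"] == 3
        assert pileup.depth[0].max() == 1

    def test_n_bases_dropped(self):
        pileup = gt.build_pileup({"S1": [_read("r", 0, "ANGT")]}, {"ref": "ACGT"})
        assert pileup.depth[0].tolist() == [1, 0, 1, 1]


class TestCallSnps:
    def test_two_samples_two_bases(self, pileup_factory):
        p = pileup_factory(["S1", "S2"], 10, {3: {"S1": {"A": 3}, "S2": {"G": 2}}})
        snps = gt.call_snps(p)
        assert len(snps) == 1
        assert snps.alleles[0].tolist() == ["ACGT".index("A"), "ACGT".index("G")]
        assert not snps.triallelic[0]

    def test_single_supporting_read_not_enough(self, pileup_factory):
        p = pileup_factory(["S1", "S2"], 10, {3: {"S1": {"A": 3}, "S2": {"G": 1}}})
        assert len(gt.call_snps(p, min_alt_reads=2)) == 0

    def test_tie_breaks_by_base_order_and_triallelic_recorded(self, pileup_factory):
        p = pileup_factory(["S1", "S2"], 10, {3: {"S1": {"A": 3, "C": 2}, "S2": {"G": 2}}})
        snps = gt.call_snps(p)
        # C and G tie on support 2; C wins by base order
        assert snps.alleles[0].tolist() == ["ACGT".index("A"), "ACGT".index("C")]
        assert snps.triallelic[0]


class TestGenotypeAtSnps:
    @pytest.fixture
    def matrix(self, pileup_factory):
        cols = {
            0: {"S1": {"A": 2, "G": 1}},            # het -> R
            1: {"S1": {"A": 1, "C": 1, "G": 1}},    # >2 alleles -> missing
            2: {"S1": {"T": 4}},                    # homozygote
            3: {"S2": {"A": 2, "G": 2}},            # S1 has no reads -> missing
        }
        p = pileup_factory(["S1", "S2"], 10, cols)
        snps = gt.SnpCalls(
            flat_positions=np.array([0, 1, 2, 3]),
            alleles=np.zeros((4, 2), np.int8),
            triallelic=np.zeros(4, bool),
        )
        return gt.genotype_at_snps(p, snps)

    def test_calls(self, matrix):
        s1 = matrix.to_strings()["S1"]
        assert s1 == "RNTN"

    def test_depths_recorded(self, matrix):
        assert matrix.depth[0].tolist() == [3, 3, 4, 0]


class TestFilterMatrix:
    def test_high_coverage_cell_masked_with_strict_inequality(self, pileup_factory):
        cols = {0: {"S1": {"A": 6}}, 1: {"S1": {"A": 5}}}
        p = pileup_factory(["S1"], 10, cols, genomewide_mean={"S1": 2.0})
        snps = gt.SnpCalls(np.array([0, 1]), np.zeros((2, 2), np.int8), np.zeros(2, bool))
        m = gt.genotype_at_snps(p, snps)
        f = gt.filter_matrix(m, p.stats, depth_multiplier=2.5, max_missing=1.0)
        # depth 6 > 5.0 masked; depth 5 == 5.0 kept (strict >)
        assert f.to_strings()["S1"] == "NA"

    def test_site_at_exactly_half_missing_is_retained(self):
        calls = np.array([[0], [4], [-1], [-1]], dtype=np.int8)
        m = gt.GenotypeMatrix(
            samples=["a", "b", "c", "d"],
            positions=[("ref", 0)],
            calls=calls,
            depth=np.ones((4, 1), np.int32),
        )
        stats = gt.CoverageStats(["a", "b", "c", "d"], 10, np.full(4, 10.0))
        f = gt.filter_matrix(m, stats, max_missing=0.5)
        assert f.n_sites == 1

    def test_sites_above_missing_threshold_dropped(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 4, size=(4, 10)).astype(np.int8)
        calls[:3, [2, 5, 9]] = gt.MISSING  # exactly 3 sites at 75% missing
        m = gt.GenotypeMatrix(
            samples=list("abcd"),
            positions=[("ref", i) for i in range(10)],
            calls=calls,
            depth=np.ones((4, 10), np.int32),
        )
        stats = gt.CoverageStats(list("abcd"), 10, np.full(4, 10.0))
        f = gt.filter_matrix(m, stats, max_missing=0.5)
        assert f.n_sites == 7

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(-1, 10, size=(5, 40)).astype(np.int8)
        depth = rng.integers(0, 12, size=(5, 40)).astype(np.int32)
        m = gt.GenotypeMatrix(
            samples=list("abcde"),
            positions=[("ref", i) for i in range(40)],
            calls=calls,
            depth=depth,
        )
        stats = gt.CoverageStats(list("abcde"), 40, rng.uniform(1, 4, 5))
        f1 = gt.filter_matrix(m, stats, max_missing=0.5)
        f2 = gt.filter_matrix(f1, stats, max_missing=0.5)
        assert f1.positions == f2.positions
        assert np.array_equal(f1.calls, f2.calls)

    def test_bad_max_missing_raises(self):
        m = gt.GenotypeMatrix(["a"], [], np.zeros((1, 0), np.int8), np.zeros((1, 0), np.int32))
        stats = gt.CoverageStats(["a"], 1, np.ones(1))
        with pytest.raises(ValueError):
            gt.filter_matrix(m, stats, max_missing=1.5)


class TestDuplicatedRegionFlag:
    def _flags(self, pileup_factory, depths):
        cols = {0: {f"S{i}": {"A": d} for i, d in enumerate(depths) if d}}
        p = pileup_factory([f"S{i}" for i in range(len(depths))], 5, cols)
        snps = gt.SnpCalls(np.array([0]), np.zeros((1, 2), np.int8), np.zeros(1, bool))
        return gt.flag_duplicated_regions(snps, p)

    def test_half_of_samples_deep_flags(self, pileup_factory):
        assert self._flags(pileup_factory, (6, 7, 2, 1))[0]

    def test_below_half_kept(self, pileup_factory):
        assert not self._flags(pileup_factory, (6, 4, 4, 4))[0]

    def test_never_flagged_at_or_below_cut(self, pileup_factory):
        assert not self._flags(pileup_factory, (5, 5, 5, 5))[0]


class TestResample:
    def _pairs(self, sample, n_pairs, pair_bases=200):
        out = []
        half = pair_bases // 2
        for i in range(n_pairs):
            out.append(_read(f"{sample}_f{i}", 0, "A" * half))
            out.append(_read(f"{sample}_f{i}", 300, "A" * half, flag=0x1 | 0x2 | 0x80))
        return out

    def test_min_sample_unchanged_and_others_at_most_target(self):
        aln = {"a": self._pairs("a", 5), "b": self._pairs("b", 10), "c": self._pairs("c", 15)}
        out = gt.resample_to_equal_bases(aln, seed=1)
        bases = {s: sum(r.aligned_length() for r in rs) for s, rs in out.items()}
        assert bases["a"] == 1000
        assert bases["b"] <= 1000 and bases["c"] <= 1000
        assert len(out["a"]) == 10  # untouched: all 5 pairs

    def test_exact_divisibility_keeps_five_pairs(self):
        aln = {"lo": self._pairs("lo", 5), "hi": self._pairs("hi", 9)}
        out = gt.resample_to_equal_bases(aln, seed=0)
        assert sum(r.aligned_length() for r in out["hi"]) == 1000

    def test_stops_before_exceeding_target(self):
        # target 990 from an odd-sized sample; 200-base pairs -> 4 kept
        lo = self._pairs("lo", 4) + [_read("lo_x", 0, "A" * 190)]
        aln = {"lo": lo, "hi": self._pairs("hi", 9)}
        out = gt.resample_to_equal_bases(aln, seed=0)
        assert sum(r.aligned_length() for r in out["hi"]) == 800

    def test_exempt_sample_passes_through(self):
        aln = {"a": self._pairs("a", 2), "b": self._pairs("b", 10)}
        out = gt.resample_to_equal_bases(aln, exempt=["a"], seed=0)
        assert len(out["a"]) == 4
        # target now defined by b alone -> b keeps everything
        assert len(out["b"]) == 20

    def test_missing_exempt_raises(self):
        with pytest.raises(ValueError, match="exempt"):
            gt.resample_to_equal_bases({"a": [], "b": []}, exempt=["zz"])

    def test_seeded_determinism(self):
        aln = {"a": self._pairs("a", 5), "b": self._pairs("b", 12)}
        r1 = gt.resample_to_equal_bases(aln, seed=9)
        r2 = gt.resample_to_equal_bases(aln, seed=9)
        assert [x.qname for x in r1["b"]] == [x.qname for x in r2["b"]]


class TestExport:
    @pytest.fixture
    def toy_matrix(self):
        calls = np.array(
            [[gt.char_to_call(c) for c in "ARN"], [gt.char_to_call(c) for c in "AAG"]],
            dtype=np.int8,
        )
        return gt.GenotypeMatrix(
            samples=["S1", "S2"],
            positions=[("ref", 4), ("ref", 9), ("ref", 12)],
            calls=calls,
            depth=np.full((2, 3), 5, np.int32),
        )

    def test_iupac_sequence_mapping(self, toy_matrix):
        assert toy_matrix.to_strings()["S1"] == "ARN"
        fasta = gt.export_iupac_alignment(toy_matrix)
        assert ">S1\nARN\n" in fasta
        phylip = gt.export_iupac_alignment(toy_matrix, fmt="phylip")
        assert phylip.splitlines()[0].split() == ["2", "3"]

    def test_het_written_as_0_1_with_ref_alt(self, toy_matrix, tmp_path):
        vcf = gt.export_vcf(toy_matrix)
        row = [l for l in vcf.splitlines() if l.startswith("ref\t10\t")][0]
        fields = row.split("\t")
        assert (fields[3], fields[4]) == ("A", "G")
        assert fields[9].startswith("0/1")

    def test_vcf_round_trip_is_identity(self, toy_matrix, tmp_path):
        path = tmp_path / "m.vcf"
        gt.export_vcf(toy_matrix, path)
        back = gt.read_vcf(path)
        assert back.samples == toy_matrix.samples
        assert back.positions == toy_matrix.positions
        assert np.array_equal(back.calls, toy_matrix.calls)
        assert np.array_equal(back.depth, toy_matrix.depth)


class TestQualityFilter:
    def test_low_quality_and_ambiguous_reads_removed_then_trimmed(self):
        q30, q10 = chr(30 + 33), chr(10 + 33)
        reads = [
            ("good", "ACGTACGTAC", q30 * 10),
            ("tail", "ACGTACGTAC", q30 * 8 + q10 * 2),
            ("bad", "ACGTACGTAC", q10 * 5 + q30 * 5),
            ("ambig", "ACGTNCGTAC", q30 * 10),
        ]
        out = gt.quality_filter_reads(reads)
        names = [r[0] for r in out]
        assert names == ["good", "tail"]
        assert len(out[1][1]) == 8  # 3' trim


class TestTruthRecovery:
    def test_depth_one_heterozygotes_collapse_without_allele_bias(self):
        cfg = sim.SimulationConfig(
            n_loci=800, locus_length=300, mutation_rate=0.01, coverage=1.0,
            read_length=100, insert_mean=220, insert_sd=30, seed=17,
        )
        truth, genomes, reads = sim.simulate(cfg)
        pileup = gt.build_pileup(
            {s: reads.sam_records(s) for s in truth.sample_names}, {"ref": genomes.reference}
        )
        # genotype at the known truth positions: discovery-free, so calls at
        # heterozygous cells are a fair draw of the two alleles (conditioning
        # on SNP discovery would enrich for the derived allele instead)
        snps = gt.SnpCalls(
            flat_positions=np.array([s.pos for s in truth.sites]),
            alleles=np.zeros((len(truth.sites), 2), np.int8),
            triallelic=np.zeros(len(truth.sites), bool),
        )
        matrix = gt.genotype_at_snps(pileup, snps)
        col_of = {pos: j for j, (_, pos) in enumerate(matrix.positions)}
        n_het_truth = n_recalled = 0
        anc_calls = der_calls = 0
        for ti, s in enumerate(truth.sites):
            het_cells = s.genotypes[:, 0] != s.genotypes[:, 1]
            n_het_truth += int(het_cells.sum())
            j = col_of.get(s.pos)
            if j is None:
                continue
            for i in np.flatnonzero(het_cells):
                call = matrix.calls[i, j]
                if call == gt.MISSING:
                    continue
                if call >= 4:
                    n_recalled += 1
                elif gt.call_to_char(call) == s.ancestral:
                    anc_calls += 1
                else:
                    der_calls += 1
        assert n_het_truth >= 1000
        # collapse: at ~1x the vast majority of heterozygous cells are lost
        # or miscalled homozygous (unseen second allele)
        assert n_recalled / n_het_truth < 0.25
        # but the surviving homozygous miscalls favor neither allele
        assert anc_calls + der_calls >= 1000
        assert binomtest(anc_calls, anc_calls + der_calls, 0.5).pvalue > 0.01
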