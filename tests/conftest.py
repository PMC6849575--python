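"""Shared fixtures: toy pileup construction and the study-scale simulation
configuration used by the calibration tests."""

from __future__ import annotations

import numpy as np
import pytest

from skimflow import genotyping as gt
from skimflow import simdata as sim


def make_pileup(
    samples: list[str],
    length: int,
    columns: dict[int, dict[str, dict[str, int]]],
    genomewide_mean: dict[str, float] | None = None,
) -> gt.Pileup:
    """Construct a single-contig pileup directly from per-column counts:
    columns[pos][sample][base] = reads."""
    counts = np.zeros((len(samples), length, 4), dtype=np.int32)
    for pos, per_sample in columns.items():
        for sname, bases in per_sample.items():
            for base, n in bases.items():
                counts[samples.index(sname), pos, "ACGT".index(base)] = n
    if genomewide_mean is None:
        means = counts.sum(axis=(1, 2)) / length
    else:
        means = np.array([genomewide_mean[s] for s in samples], dtype=float)
    stats = gt.CoverageStats(samples=list(samples), reference_length=length, genomewide_mean=means)
    return gt.Pileup(
        samples=list(samples),
        ref_names=["ref"],
        ref_lengths={"ref": length},
        offsets={"ref": 0},
        counts=counts,
        stats=stats,
    )


@pytest.fixture
def pileup_factory():
    return make_pileup


def calibration_config(seed: int, gamma: float = 0.0) -> sim.SimulationConfig:
    """The scaled study conditions used for pipeline calibration: a 4-tip
    quartet with substantial incomplete lineage sorting, 500 loci of
    300 bp, one diploid sample per tip, 8x error-free coverage."""
    events = (
        [sim.IntrogressionEvent(donor="P2", recipient="P3", time=0.1, proportion=gamma)]
        if gamma > 0
        else []
    )
    return sim.SimulationConfig(
        n_loci=500,
        locus_length=300,
        mutation_rate=0.01,
        coverage=8.0,
        read_length=100,
        insert_mean=220,
        insert_sd=30,
        error_rate=0.0,
        seed=seed,
        introgression_events=events,
    )


def run_pipeline_z(seed: int, gamma: float) -> float:
    """simulate -> genotype -> filter -> D with jackknife; returns Z."""
    from skimflow import dstat as ds

    truth, genomes, reads = sim.simulate(calibration_config(seed, gamma))
    pileup = gt.build_pileup(
        {s: reads.sam_records(s) for s in truth.sample_names}, {"ref": genomes.reference}
    )
    snps = gt.call_snps(pileup)
    matrix = gt.filter_matrix(gt.genotype_at_snps(pileup, snps), pileup.stats, max_missing=0.5)
    counts = ds.count_site_patterns(
        matrix, ds.QuartetSpec("P1", "P2", "P3", "O"), block_size=500, seed=seed
    )
    return ds.jackknife_z(counts).z
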