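"""ABBA-BABA introgression tests.

For an ordered quartet (P1, P2, P3, Outgroup) laid out as
(Outgroup,(P3,(P2,P1))), incomplete lineage sorting produces the two
discordant biallelic site patterns ABBA (P2 and P3 share the derived
allele) and BABA (P1 and P3 share it) at equal expected frequency; an
introgression pulse between P3 and either P1 or P2 breaks the symmetry.
Patterson's D = (nABBA - nBABA) / (nABBA + nBABA) measures the asymmetry,
and a delete-one block jackknife over contiguous SNP blocks yields a
standard error robust to linkage, hence a Z score and two-sided normal p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .genotyping import _CALL_CHAR, HET_SETS, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QuartetSpec:
    """Sample labels for one test, plus the heterozygote handling mode.

    mode="sampled" draws one allele per heterozygous call uniformly at
    random (seeded), emulating per-read pattern counting from low-coverage
    data; mode="majority" uses fixed genotype calls only and skips sites
    where any quartet member is heterozygous (a diploid heterozygote has
    no majority base).
    """

    p1: str
    p2: str
    p3: str
    outgroup: str
    mode: str = "sampled"

    def __post_init__(self) -> None:
        names = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(names)) != 4:
            raise ValueError("quartet requires four distinct sample names")
        if self.mode not in ("sampled", "majority"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class QuartetCounts:
    blocks: list[tuple[int, int]]  # per-block (nABBA, nBABA)
    block_size: int | None = None
    quartet: QuartetSpec | None = None
    jackknife_ok: bool = True

    @property
    def n_abba(self) -> int:
        return sum(b[0] for b in self.blocks)

    @property
    def n_baba(self) -> int:
        return sum(b[1] for b in self.blocks)


@dataclass
class DStatResult:
    quartet: QuartetSpec | None
    n_abba: int
    n_baba: int
    d: float
    se: float = math.nan
    z: float = math.nan
    p: float = math.nan
    n_blocks: int = 0
    jackknife_disabled: bool = False
    p_bonferroni: float | None = None
    significant: bool | None = None

    def conclusion(self) -> str:
        if self.jackknife_disabled or math.isnan(self.z):
            return "no jackknife (too few blocks)"
        sig = self.significant
        if sig is None:
            sig = self.p < 0.05
        if not sig:
            return "no significant asymmetry (ILS-compatible)"
        closer = ("P2", "P3") if self.d > 0 else ("P1", "P3")
        return f"{closer[0]} shares excess derived alleles with {closer[1]} (gene flow)"

    def summary(self) -> str:
        q = self.quartet
        head = f"{q.p1},{q.p2},{q.p3}|{q.outgroup}" if q else "quartet"
        return (
            f"{head}: ABBA={self.n_abba} BABA={self.n_baba} "
            f"D={self.d:.3f} Z={self.z:.3f} p={self.p:.3g} -> {self.conclusion()}"
        )


# decode call code -> (allele_a, allele_b) base codes; -1 rows for missing
_DECODE = np.full((11, 2), -1, dtype=np.int8)
for _c in range(4):
    _DECODE[_c] = (_c, _c)
for _c in range(4, 10):
    _a, _b = sorted("ACGT".index(x) for x in HET_SETS[_CALL_CHAR[_c]])
    _DECODE[_c] = (_a, _b)


def count_site_patterns(
    matrix: GenotypeMatrix,
    quartet: QuartetSpec,
    block_size: int = 500,
    seed: int | None = None,
) -> QuartetCounts:
    """Count ABBA and BABA patterns per block of consecutive SNPs.

    Sites with a missing call in any quartet member are skipped, as are
    sites where the outgroup is heterozygous (the outgroup allele defines
    the ancestral state) and sites that are not biallelic within the
    quartet. Blocks are consecutive runs of `block_size` counted-or-skipped
    positions in matrix order, so D (though not its SE) is invariant to
    the block size.
    """
    for name in (quartet.p1, quartet.p2, quartet.p3, quartet.outgroup):
        if name not in matrix.samples:
            raise ValueError(f"quartet sample {name!r} absent from the matrix")
    rng = np.random.default_rng(seed)
    idx = [matrix.samples.index(n) for n in (quartet.p1, quartet.p2, quartet.p3, quartet.outgroup)]
    calls = matrix.calls[idx]  # (4, n_sites)
    n_sites = calls.shape[1]
    if n_sites == 0:
        return QuartetCounts(blocks=[], block_size=block_size, quartet=quartet, jackknife_ok=False)

    codes = calls.copy()
    codes[codes == MISSING] = 10
    pairs = _DECODE[codes]  # (4, n_sites, 2)
    valid = (calls != MISSING).all(axis=0)
    out_het = calls[3] >= 4
    valid &= ~out_het

    if quartet.mode == "sampled":
        pick = rng.integers(0, 2, size=(4, n_sites))
        bases = np.take_along_axis(pairs, pick[:, :, None], axis=2)[:, :, 0]
    else:
        any_het = (calls >= 4).any(axis=0)
        valid &= ~any_het
        bases = pairs[:, :, 0]

    anc = bases[3]
    is_anc = bases == anc[None, :]
    # biallelic within the quartet: all non-ancestral bases identical
    derived = np.where(is_anc, -1, bases)
    dmax = derived.max(axis=0)
    biallelic = (dmax >= 0) & ((derived < 0) | (derived == dmax[None, :])).all(axis=0)
    valid &= biallelic

    abba = valid & is_anc[0] & ~is_anc[1] & ~is_anc[2]
    baba = valid & ~is_anc[0] & is_anc[1] & ~is_anc[2]

    blocks = []
    for start in range(0, n_sites, block_size):
        sl = slice(start, start + block_size)
        blocks.append((int(abba[sl].sum()), int(baba[sl].sum())))
    nonempty = sum(1 for a, b in blocks if a + b > 0)
    return QuartetCounts(
        blocks=blocks, block_size=block_size, quartet=quartet, jackknife_ok=nonempty >= 2
    )


def d_statistic(counts: QuartetCounts | tuple[int, int]) -> float:
    """Patterson's D = (nABBA - nBABA) / (nABBA + nBABA)."""
    if isinstance(counts, QuartetCounts):
        a, b = counts.n_abba, counts.n_baba
    else:
        a, b = counts
    if a + b == 0:
        raise ValueError("no informative sites")
    return (a - b) / (a + b)


def jackknife_z(counts: QuartetCounts) -> DStatResult:
    """Delete-one-block jackknife for D.

    Each non-empty block is removed in turn and D recomputed on the pooled
    remaining counts; with m blocks,
    SE = sqrt((m-1)/m * sum_i (D_(i) - mean D_(i))^2), Z = D/SE, and p is
    the two-sided normal tail probability.
    """
    d = d_statistic(counts)
    nonempty = [(a, b) for a, b in counts.blocks if a + b > 0]
    m = len(nonempty)
    base = DStatResult(
        quartet=counts.quartet, n_abba=counts.n_abba, n_baba=counts.n_baba, d=d, n_blocks=m
    )
    if m < 2 or not counts.jackknife_ok:
        base.jackknife_disabled = True
        return base
    tot_a, tot_b = counts.n_abba, counts.n_baba
    d_del = np.array([(tot_a - a - (tot_b - b)) / (tot_a - a + tot_b - b) for a, b in nonempty])
    se = math.sqrt((m - 1) / m * np.sum((d_del - d_del.mean()) ** 2))
    base.se = se
    if se == 0.0:
        if d == 0.0:
            base.z, base.p = 0.0, 1.0
        else:
            warnings.warn(
                "jackknife SE is zero (identical delete-one estimates); Z reported as inf",
                stacklevel=2,
            )
            base.z, base.p = math.copysign(math.inf, d), 0.0
        return base
    base.z = d / se
    base.p = 2.0 * _st.norm.sf(abs(base.z))
    return base


def bonferroni(results: Sequence[DStatResult], m_tests: int | None = None) -> list[DStatResult]:
    """Bonferroni correction: p_bonferroni = min(1, p * m); significance at
    the 0.05 level. m defaults to the number of results in the batch."""
    m = len(results) if m_tests is None else m_tests
    if m < len(results):
        raise ValueError("m_tests must be at least the number of results")
    for r in results:
        if not math.isnan(r.p):
            r.p_bonferroni = min(1.0, r.p * m)
            r.significant = r.p_bonferroni < 0.05
    return list(results)


def results_table(results: Sequence[DStatResult]) -> pd.DataFrame:
    """Tabulate results in the layout of a published ABBA-BABA table."""
    rows = []
    for r in results:
        q = r.quartet
        rows.append(
            {
                "Outgroup": q.outgroup if q else "",
                "P3": q.p3 if q else "",
                "P2": q.p2 if q else "",
                "P1": q.p1 if q else "",
                "nABBA": r.n_abba,
                "nBABA": r.n_baba,
                "D": round(r.d, 3),
                "Z": round(r.z, 3) if not math.isnan(r.z) else float("nan"),
                "p": r.p,
                "p_bonferroni": r.p_bonferroni,
                "conclusion": r.conclusion(),
            }
        )
    return pd.DataFrame(rows)
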