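"""Population-structure and phylogenetic summaries.

Evanno's delta-K over cluster-run log-likelihood tables, per-sample
heterozygosity from the genotype matrix, IUPAC-aware p-distances, and a
deterministic neighbor-joining tree. The clustering MCMC itself is out of
scope — only its summary statistics are computed here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import _CALL_CHAR, HET_SETS, MISSING, GenotypeMatrix

# base sets per IUPAC character used in alignments
_IUPAC_SET = {b: frozenset(b) for b in "ACGT"}
_IUPAC_SET.update({c: frozenset(s) for c, s in HET_SETS.items()})


@dataclass
class EvannoTable:
    table: pd.DataFrame  # columns: K, n_runs, mean_L, sd_L, Lprime, Lsecond, deltaK
    best_k: int

    def __repr__(self) -> str:
        return f"EvannoTable(best_k={self.best_k})\n{self.table}"


def evanno(runs: pd.DataFrame) -> EvannoTable:
    """Evanno's delta-K from per-run cluster log-likelihoods.

    `runs` needs columns K, run, lnL with a contiguous K range of length
    >= 3 and >= 2 runs per K. Per K: L'(K) = mean lnL(K) - mean lnL(K-1),
    |L''(K)| = |L'(K+1) - L'(K)|, deltaK = |L''(K)| / sd(lnL(K)) with the
    sample standard deviation over runs. L' is undefined at the smallest
    K; |L''| and deltaK additionally at the largest.
    """
    req = {"K", "run", "lnL"}
    if not req.issubset(runs.columns):
        raise ValueError(f"run table needs columns {sorted(req)}")
    ks = np.sort(runs["K"].unique())
    if len(ks) < 3:
        raise ValueError("Evanno's method needs a K range of length >= 3")
    if not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ValueError("K values must form a contiguous range")
    grp = runs.groupby("K")["lnL"]
    n_runs = grp.size()
    if (n_runs < 2).any():
        bad = n_runs[n_runs < 2].index.tolist()
        raise ValueError(
            f"at least 2 runs per K are required for the SD (single run at K={bad}); rerun the clustering"
        )
    mean_l = grp.mean().reindex(ks)
    sd_l = grp.std(ddof=1).reindex(ks)
    lprime = mean_l.diff()
    lsecond = lprime.shift(-1).sub(lprime).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = lsecond / sd_l
    if ((sd_l == 0) & lsecond.notna()).any():
        warnings.warn("sd(lnL)=0 at some K; deltaK reported as inf there", stacklevel=2)
    tab = pd.DataFrame(
        {
            "K": ks,
            "n_runs": n_runs.reindex(ks).to_numpy(),
            "mean_L": mean_l.to_numpy(),
            "sd_L": sd_l.to_numpy(),
            "Lprime": lprime.to_numpy(),
            "Lsecond": lsecond.to_numpy(),
            "deltaK": delta.to_numpy(),
        }
    )
    defined = tab["deltaK"].notna()
    best_k = int(tab.loc[defined, "deltaK"].idxmax())
    best_k = int(tab.loc[best_k, "K"])
    return EvannoTable(table=tab, best_k=best_k)


def read_cluster_runs(path) -> pd.DataFrame:
    """Read a (K, run, lnL) TSV as produced by clustering wrappers."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    return df


def heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Fraction of heterozygous calls among non-missing calls, per sample.

    Low coverage biases this downward (unseen alleles make heterozygotes
    look homozygous) but comparably so across samples sequenced to similar
    depth, so between-sample comparisons remain meaningful.
    """
    called = matrix.calls != MISSING
    het = matrix.calls >= 4
    n_called = called.sum(axis=1)
    out = {}
    for i, s in enumerate(matrix.samples):
        if n_called[i] == 0:
            warnings.warn(f"sample {s!r} has no called sites; omitted", stacklevel=2)
            continue
        out[s] = het[i].sum() / n_called[i]
    return pd.Series(out, name="heterozygosity")


def p_distance(seqs: dict[str, str]) -> pd.DataFrame:
    """Pairwise p-distances over IUPAC-coded sequences.

    Columns where either sequence is N or a gap are ignored. Identical
    codes score 0; a code whose base set intersects the other's (e.g. R vs
    G) scores 0.5; disjoint sets score 1. Distances are fractions of
    compared columns.
    """
    names = list(seqs)
    lens = {len(s) for s in seqs.values()}
    if len(lens) > 1:
        raise ValueError("sequences must be aligned to equal length")
    n = len(names)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_p_distance(seqs[names[i]], seqs[names[j]])
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def pairwise_p_distance(a: str, b: str) -> float:
    compared = 0
    diff = 0.0
    for x, y in zip(a.upper(), b.upper()):
        sx = _IUPAC_SET.get(x)
        sy = _IUPAC_SET.get(y)
        if sx is None or sy is None:  # N, gap, anything unknown
            continue
        compared += 1
        if sx == sy:
            continue
        diff += 0.5 if sx & sy else 1.0
    return diff / compared if compared else float("nan")


def nj_tree(dist: pd.DataFrame) -> str:
    """Neighbor joining by the classical Q criterion.

    Deterministic: ties in Q break lexicographically on the (sorted) pair
    of clade names; negative branch lengths are clamped to zero. Returns
    an unrooted Newick string (trifurcating root).
    """
    names = list(dist.index)
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    d = {a: {b: float(dist.loc[a, b]) for b in names} for a in names}
    newick = {a: a for a in names}
    leafset = {a: a for a in names}  # node -> lexicographically least leaf
    active = sorted(names)

    while len(active) > 3:
        r = len(active)
        totals = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (r - 2) * d[a][b] - totals[a] - totals[b]
            key = (q, *sorted((leafset[a], leafset[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        va = 0.5 * d[a][b] + (totals[a] - totals[b]) / (2 * (r - 2))
        vb = d[a][b] - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        u = f"__u{len(d)}"
        d[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[u][c] = d[c][u] = max(duc, 0.0)
        d[u][u] = 0.0
        newick[u] = f"({newick[a]}:{va:.6f},{newick[b]}:{vb:.6f})"
        leafset[u] = min(leafset[a], leafset[b])
        active = sorted(
            (c for c in active if c not in (a, b)), key=lambda c: leafset[c]
        ) + [u]
        active.sort(key=lambda c: leafset[c])

    a, b, c = sorted(active, key=lambda x: leafset[x])
    va = max(0.5 * (d[a][b] + d[a][c] - d[b][c]), 0.0)
    vb = max(0.5 * (d[a][b] + d[b][c] - d[a][c]), 0.0)
    vc = max(0.5 * (d[a][c] + d[b][c] - d[a][b]), 0.0)
    return f"({newick[a]}:{va:.6f},{newick[b]}:{vb:.6f},{newick[c]}:{vc:.6f});"


def align_cluster_labels(q_matrices: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Greedy label alignment across clustering runs at one K.

    Cluster labels are arbitrary per run; columns of each later run are
    permuted to best match the first run by correlation, greedily from the
    strongest match down. A lightweight stand-in for full label-switching
    search, sufficient for averaging assignment fractions across runs.
    """
    if not q_matrices:
        return []
    ref = q_matrices[0]
    out = [ref]
    k = ref.shape[1]
    for q in q_matrices[1:]:
        if q.shape != ref.shape:
            raise ValueError("all Q matrices must have identical shape")
        corr = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    c = np.corrcoef(ref.iloc[:, i], q.iloc[:, j])[0, 1]
                corr[i, j] = -2.0 if np.isnan(c) else c
        perm = [-1] * k
        used_i, used_j = set(), set()
        for _ in range(k):
            best = max(
                ((corr[i, j], i, j) for i in range(k) for j in range(k)
                 if i not in used_i and j not in used_j),
            )
            _, i, j = best
            perm[i] = j
            used_i.add(i)
            used_j.add(j)
        out.append(q.iloc[:, perm].set_axis(ref.columns, axis=1))
    return out
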