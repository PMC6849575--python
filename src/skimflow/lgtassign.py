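"""Phylogenetic read assignment against a labeled gene-lineage panel.

Detects laterally acquired gene copies in genome-skimming reads by a
four-step procedure: (i) a reference panel of aligned sequences from
closely related gene lineages, each labeled with its lineage (e.g. the
vertically inherited copy vs. copies acquired from distinct donor groups);
(ii) a homology screen of every read (both strands) against the panel;
(iii) per-read placement — the read is threaded into the panel alignment
at its best hit, pairwise p-distances are computed over the overlapping
columns, and a neighbor-joining tree of panel-plus-read is built; (iv) the
read is assigned to the lineage in whose clade it nests, or left
unassigned when placement is ambiguous. Per-sample read counts over exon
partitions then yield presence / absence / truncation calls per gene copy.

Assignment is fully deterministic: no randomness enters at any step.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from skbio import TreeNode

from .popphylo import nj_tree, p_distance, pairwise_p_distance
from .simdata import revcomp

UNASSIGNED = "UNASSIGNED"


@dataclass
class ReferencePanel:
    """Aligned gene-lineage sequences with lineage labels and an optional
    exon-partition map (alignment coordinates, 0-based half-open)."""

    aligned: dict[str, str]
    lineage: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned.values()}
        if len(lengths) > 1:
            raise ValueError("panel sequences must be aligned to equal length")
        self.aln_len = lengths.pop() if lengths else 0
        missing = set(self.aligned) - set(self.lineage)
        if missing:
            raise ValueError(f"unlabeled panel sequences: {sorted(missing)}")
        for name, start, end in self.partitions:
            if not (0 <= start < end <= self.aln_len):
                raise ValueError(f"partition {name!r} outside the alignment")
        spans = sorted((s, e) for _, s, e in self.partitions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("partitions must not overlap")
        self._ungapped: dict[str, str] = {}
        self._col_of: dict[str, np.ndarray] = {}
        for name, seq in self.aligned.items():
            cols = np.array([i for i, ch in enumerate(seq) if ch != "-"], dtype=np.int64)
            self._ungapped[name] = seq.replace("-", "")
            self._col_of[name] = cols
        self._panel_dist: pd.DataFrame | None = None

    @property
    def names(self) -> list[str]:
        return list(self.aligned)

    @property
    def lineages(self) -> list[str]:
        return sorted(set(self.lineage.values()))

    def ungapped(self, name: str) -> str:
        return self._ungapped[name]

    def column_of(self, name: str, ungapped_pos: int) -> int:
        return int(self._col_of[name][ungapped_pos])

    def pairwise_distances(self) -> pd.DataFrame:
        if self._panel_dist is None:
            self._panel_dist = p_distance(self.aligned)
        return self._panel_dist

    def effective_partitions(self) -> list[tuple[str, int, int]]:
        return self.partitions or [("all", 0, self.aln_len)]

    @classmethod
    def from_files(cls, fasta, labels_tsv, partitions_bed=None) -> "ReferencePanel":
        """Panel from an aligned FASTA, a (sequence, lineage) TSV sidecar,
        and an optional BED-like partition file (name, start, end columns
        in alignment coordinates)."""
        from .io import read_fasta

        aligned = read_fasta(fasta)
        labels = pd.read_csv(labels_tsv, sep="\t", header=None, comment="#")
        lineage = dict(zip(labels[0].astype(str), labels[1].astype(str)))
        partitions = []
        if partitions_bed is not None:
            bed = pd.read_csv(partitions_bed, sep="\t", header=None, comment="#")
            for _, row in bed.iterrows():
                partitions.append((str(row[3]) if len(row) > 3 else str(row[0]),
                                   int(row[1]), int(row[2])))
        return cls(aligned=aligned, lineage=lineage, partitions=partitions)


@dataclass
class CandidateHit:
    read_id: str
    seq: str  # original read orientation
    strand: str  # "+" or "-"
    target: str  # panel sequence name
    target_start: int  # ungapped target coordinates, half-open
    target_end: int
    cigar: str
    identity: float
    matched_len: int  # aligned target span in bp


@dataclass
class ReadAssignment:
    read_id: str
    sample: str
    lineage: str  # label or UNASSIGNED
    aligned_span: tuple[int, int] | None = None  # alignment columns, half-open
    identity_to_best: float = float("nan")
    placement_support: float = float("nan")
    reason: str = ""


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment_length) from an edlib extended CIGAR."""
    matches = total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            total += n
            if ch == "=":
                matches += n
    return matches, total


def find_homologous_reads(
    reads: Iterable[tuple[str, str]],
    panel: ReferencePanel,
    min_len: int = 50,
    min_identity: float = 0.90,
) -> tuple[list[CandidateHit], int]:
    """Screen reads against every panel sequence on both strands.

    Each read is aligned (semi-global: the full read within the panel
    sequence) to every panel sequence and its reverse complement; it
    becomes a candidate when its best alignment spans >= `min_len` target
    bp at >= `min_identity`. Identity is matches over alignment columns.
    The strict setting min_identity=0.99 reproduces a 50 bp / 99% homology
    screen; 0.90 is the default discovery mode. Returns (candidates,
    n_too_short).
    """
    candidates: list[CandidateHit] = []
    n_short = 0
    targets = [(name, panel.ungapped(name)) for name in panel.names]
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < min_len:
            n_short += 1
            continue
        best: tuple | None = None
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for name, target in targets:
                if len(target) < min_len:
                    continue
                res = edlib.align(query, target, mode="HW", task="path",
                                  k=int(len(query) * (1 - min_identity) * 2) + 2)
                if res["editDistance"] < 0:
                    continue
                matches, total = _cigar_stats(res["cigar"])
                identity = matches / total if total else 0.0
                t0, t1 = res["locations"][0]
                span = t1 - t0 + 1
                key = (-identity, -span, name, strand)
                if best is None or key < best[0]:
                    best = (key, CandidateHit(
                        read_id=read_id, seq=seq, strand=strand, target=name,
                        target_start=t0, target_end=t1 + 1, cigar=res["cigar"],
                        identity=identity, matched_len=span,
                    ))
        if best is not None:
            hit = best[1]
            if hit.matched_len >= min_len and hit.identity >= min_identity:
                candidates.append(hit)
    return candidates, n_short


def _thread_read(hit: CandidateHit, panel: ReferencePanel) -> dict[int, str]:
    """Map the read's bases onto panel alignment columns via its best hit."""
    query = hit.seq if hit.strand == "+" else revcomp(hit.seq)
    cols: dict[int, str] = {}
    qpos, tpos = 0, hit.target_start
    num = ""
    for ch in hit.cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for k in range(n):
                cols[panel.column_of(hit.target, tpos + k)] = query[qpos + k]
            qpos += n
            tpos += n
        elif ch == "I":  # read base absent from the target: no column
            qpos += n
        elif ch == "D":  # target base absent from the read
            tpos += n
    return cols


def _splits(tree: TreeNode) -> list[frozenset]:
    tips = frozenset(t.name for t in tree.tips())
    out = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 0 < len(side) < len(tips):
            out.append(side)
    return out


def place_read(
    hit: CandidateHit,
    panel: ReferencePanel,
    min_overlap: int = 50,
    epsilon: float = 0.005,
    branch_ratio: float = 2.0,
    sample: str = "",
) -> ReadAssignment:
    """Place one candidate read and assign it to a gene lineage.

    The read is threaded into the panel alignment, p-distances to every
    panel sequence are computed over the overlapping columns, and a
    neighbor-joining tree of panel-plus-read is built. The read is
    assigned to the label of the smallest labeled clade it nests within,
    provided (a) that label also minimizes the read-to-lineage distance,
    with the margin to the second-closest lineage >= `epsilon`, and (b) a
    sister-to-clade attachment passes the branch-ratio test (read pendant
    branch < `branch_ratio` x clade depth). Anything else is UNASSIGNED
    with a reason.
    """
    cols = _thread_read(hit, panel)
    span = (min(cols), max(cols) + 1) if cols else None
    base = ReadAssignment(read_id=hit.read_id, sample=sample, lineage=UNASSIGNED,
                          aligned_span=span, identity_to_best=hit.identity)

    # read-to-panel distances over overlapping columns
    dists: dict[str, float] = {}
    overlaps: dict[str, int] = {}
    for name, aseq in panel.aligned.items():
        sub_read = []
        sub_panel = []
        for c, b in cols.items():
            pch = aseq[c]
            if pch != "-":
                sub_read.append(b)
                sub_panel.append(pch)
        overlaps[name] = len(sub_read)
        if sub_read:
            dists[name] = pairwise_p_distance("".join(sub_read), "".join(sub_panel))
    usable = [n for n in panel.names if overlaps.get(n, 0) >= min_overlap]
    if not usable:
        base.reason = "overlap below minimum"
        return base

    by_lineage: dict[str, float] = {}
    for n in usable:
        lab = panel.lineage[n]
        d = dists[n]
        if lab not in by_lineage or d < by_lineage[lab]:
            by_lineage[lab] = d
    ranked = sorted(by_lineage.items(), key=lambda kv: (kv[1], kv[0]))
    best_lab, d1 = ranked[0]
    support = (ranked[1][1] - d1) if len(ranked) > 1 else float("inf")
    base.placement_support = support
    if support < epsilon:
        base.reason = "distance tie between lineages"
        return base
    if len(ranked) == 1:
        base.lineage = best_lab
        base.reason = "single usable lineage"
        return base

    if len(usable) < 3:
        base.lineage = best_lab
        base.reason = "distance only (too few sequences for a tree)"
        return base

    # neighbor-joining placement
    sub = panel.pairwise_distances().loc[usable, usable].copy()
    q = "__QUERY__"
    row = pd.Series({n: dists[n] for n in usable}, name=q)
    sub.loc[q, usable] = row
    sub.loc[usable, q] = row
    sub.loc[q, q] = 0.0
    newick = nj_tree(sub)
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    tips_all = frozenset(t.name for t in tree.tips())
    splits = _splits(tree)
    sides = set(splits) | {tips_all - s for s in splits}

    read_tip = next(t for t in tree.tips() if t.name == q)
    pendant = read_tip.length or 0.0

    chosen: tuple[int, str] | None = None  # (clade size, label); nested beats sister
    chosen_sister: tuple[int, str] | None = None
    for lab in sorted(set(panel.lineage[n] for n in usable)):
        members = frozenset(n for n in usable if panel.lineage[n] == lab)
        rest = tips_all - members - {q}
        if not rest:
            continue
        grouped = frozenset(members | {q})
        if grouped != tips_all and (grouped in sides or len(members) + 1 == len(tips_all)):
            # read attaches on or inside the clade; inside iff a proper
            # sub-split mixes the read with part of the clade
            inside = any(
                (q in s) and s < grouped and len(s) > 1 for s in sides
            )
            if inside:
                if chosen is None or len(members) < chosen[0]:
                    chosen = (len(members), lab)
            else:
                # sister attachment: branch-ratio test against the clade depth
                member_tips = [t for t in tree.tips() if t.name in members]
                if len(member_tips) >= 2:
                    depth = max(
                        a.distance(b) for a, b in itertools.combinations(member_tips, 2)
                    ) / 2.0
                else:
                    depth = member_tips[0].length or 0.0
                if depth > 0 and pendant < branch_ratio * depth:
                    if chosen_sister is None or len(members) < chosen_sister[0]:
                        chosen_sister = (len(members), lab)

    pick = chosen or chosen_sister
    if pick is None:
        base.reason = "read attaches outside all labeled clades"
        return base
    if pick[1] != best_lab:
        base.reason = "tree placement conflicts with nearest lineage"
        return base
    base.lineage = pick[1]
    base.reason = "nested" if chosen else "sister (branch-ratio pass)"
    return base


def _pair_key(read_id: str) -> str:
    for suffix in ("/1", "/2", ".1", ".2", "_1", "_2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def assign_reads(
    reads: Iterable[tuple[str, str]],
    panel: ReferencePanel,
    sample: str = "",
    min_len: int = 50,
    min_identity: float = 0.90,
    min_overlap: int = 50,
    epsilon: float = 0.005,
) -> list[ReadAssignment]:
    """Homology screen + placement for a sample's reads, with mates of a
    pair assigned independently and demoted to UNASSIGNED when their
    lineage assignments conflict (conservative)."""
    candidates, _ = find_homologous_reads(reads, panel, min_len=min_len, min_identity=min_identity)
    assignments = [
        place_read(hit, panel, min_overlap=min_overlap, epsilon=epsilon, sample=sample)
        for hit in candidates
    ]
    by_pair: dict[str, list[ReadAssignment]] = {}
    for a in assignments:
        by_pair.setdefault(_pair_key(a.read_id), []).append(a)
    for members in by_pair.values():
        labs = {a.lineage for a in members if a.lineage != UNASSIGNED}
        if len(labs) > 1:
            for a in members:
                a.lineage = UNASSIGNED
                a.reason = "mate-pair lineage conflict"
    return assignments


@dataclass
class GenePresenceReport:
    table: pd.DataFrame  # sample, lineage, per-partition counts, total, status

    def presence_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="sample", columns="lineage", values="total").fillna(0).astype(int)

    def status_of(self, sample: str, lineage: str) -> str:
        sel = self.table[(self.table["sample"] == sample) & (self.table["lineage"] == lineage)]
        return sel["status"].iloc[0] if len(sel) else "absent"


def summarize_gene_presence(
    assignments: Sequence[ReadAssignment],
    panel: ReferencePanel,
    min_reads: int = 1,
) -> GenePresenceReport:
    """Presence / absence / truncation per (sample, lineage).

    Each assigned read is counted toward the exon partition its aligned
    span overlaps most (ties to the first listed). A copy is present when
    its total count reaches `min_reads`; it is truncated when one
    partition reaches `min_reads` while another has no reads at all —
    the signature of a partial (pseudogenized) copy.
    """
    parts = panel.effective_partitions()
    samples = sorted({a.sample for a in assignments})
    rows = []
    for sample in samples:
        for lineage in panel.lineages:
            counts = {p[0]: 0 for p in parts}
            for a in assignments:
                if a.sample != sample or a.lineage != lineage or a.aligned_span is None:
                    continue
                s, e = a.aligned_span
                best_part, best_ov = None, 0
                for pname, ps, pe in parts:
                    ov = max(0, min(e, pe) - max(s, ps))
                    if ov > best_ov:
                        best_part, best_ov = pname, ov
                if best_part is not None:
                    counts[best_part] += 1
            total = sum(counts.values())
            if total < min_reads:
                status = "absent"
            elif (
                len(parts) >= 2
                and any(c >= min_reads for c in counts.values())
                and any(c == 0 for c in counts.values())
            ):
                status = "truncated"
            else:
                status = "present"
            rows.append({"sample": sample, "lineage": lineage, **counts,
                         "total": total, "status": status})
    return GenePresenceReport(table=pd.DataFrame(rows))
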