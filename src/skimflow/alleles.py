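"""Per-sample gene-model (allele) assembly from reads on one gene.

Distinct alleles are only asserted when supported by at least two
different polymorphic sites, each with at least two independent fragments
per base (a mate pair counts as one fragment). With sufficient support the
fragments are phased by two-coloring a co-occurrence graph; otherwise a
single consensus is emitted with residual polymorphism written as IUPAC
ambiguity codes. The procedure is deterministic — no randomness anywhere.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genotyping import IUPAC_PAIRS
from .io import AlignedRead

Fragment = Mapping[int, str]  # reference position -> base


@dataclass
class SupportedSite:
    pos: int
    base1: str
    base2: str
    fragments1: frozenset
    fragments2: frozenset


@dataclass
class AlleleModel:
    sample: str
    gene: str
    alleles: list[str]  # 1 or 2 sequences over {A,C,G,T,IUPAC,N}
    polymorphic_sites: list[SupportedSite]
    phased_fragments: list[frozenset] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def fragments_from_alignments(records: Sequence[AlignedRead]) -> dict[str, dict[int, str]]:
    """Collapse SAM records into fragments keyed by query name: mates of a
    pair merge into one fragment; a position where mates disagree is
    dropped from the fragment."""
    frags: dict[str, dict[int, str]] = {}
    conflict: dict[str, set[int]] = defaultdict(set)
    for rec in records:
        if rec.is_unmapped:
            continue
        frag = frags.setdefault(rec.qname, {})
        for pos, base in rec.aligned_pairs():
            if base not in "ACGT":
                continue
            if pos in frag and frag[pos] != base:
                conflict[rec.qname].add(pos)
            else:
                frag[pos] = base
    for qname, bad in conflict.items():
        for pos in bad:
            frags[qname].pop(pos, None)
    return frags


def detect_supported_polymorphisms(
    fragments: Mapping[str, Fragment], min_fragments: int = 2
) -> tuple[list[SupportedSite], list[int]]:
    """Sites where exactly two bases are each carried by >= `min_fragments`
    distinct fragments. Sites where three or more bases clear the bar are
    flagged and excluded (returned separately)."""
    by_pos: dict[int, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for fid, frag in fragments.items():
        for pos, base in frag.items():
            by_pos[pos][base].add(fid)
    supported: list[SupportedSite] = []
    excluded: list[int] = []
    for pos in sorted(by_pos):
        qualifying = {b: ids for b, ids in by_pos[pos].items() if len(ids) >= min_fragments}
        if len(qualifying) == 2:
            (b1, ids1), (b2, ids2) = sorted(qualifying.items())
            supported.append(
                SupportedSite(pos=pos, base1=b1, base2=b2,
                              fragments1=frozenset(ids1), fragments2=frozenset(ids2))
            )
        elif len(qualifying) >= 3:
            excluded.append(pos)
    return supported, excluded


def _call_column(col: Mapping[str, int] | None) -> str:
    """Majority base of one column; a two-way tie becomes the IUPAC code,
    wider ties or no coverage become N."""
    if not col:
        return "N"
    best = max(col.values())
    tops = sorted(b for b, c in col.items() if c == best)
    if len(tops) == 1:
        return tops[0]
    if len(tops) == 2:
        return IUPAC_PAIRS.get(frozenset(tops), "N")
    return "N"


def _consensus(
    columns: Mapping[int, Mapping[str, int]],
    length: int,
    iupac_at: Mapping[int, tuple[str, str]] | None = None,
) -> str:
    """Majority consensus; ties become IUPAC codes; forced IUPAC at
    `iupac_at` positions; uncovered positions are N."""
    iupac_at = iupac_at or {}
    out = []
    for pos in range(length):
        if pos in iupac_at:
            out.append(IUPAC_PAIRS.get(frozenset(iupac_at[pos]), "N"))
        else:
            out.append(_call_column(columns.get(pos)))
    return "".join(out)


def _columns_of(fragments: Mapping[str, Fragment], ids) -> dict[int, dict[str, int]]:
    cols: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for fid in ids:
        for pos, base in fragments[fid].items():
            cols[pos][base] += 1
    return cols


def phase_alleles(
    fragments: Mapping[str, Fragment],
    sites: Sequence[SupportedSite],
    ref_length: int,
    sample: str = "",
    gene: str = "",
) -> AlleleModel:
    """Assemble one or two allele sequences from fragments.

    Fewer than two supported polymorphic sites forbid a second model: a
    single consensus is emitted with the supported sites (if any) as IUPAC
    codes. With two or more sites, fragments sharing a supported site are
    linked — same base, same haplotype; different base, opposite — and
    the resulting parity graph is two-colored. Fragments touching no
    supported site contribute to both alleles. An inconsistent linkage
    (odd cycle) falls back to the single-consensus output with a warning.
    """
    notes: list[str] = []
    single_iupac = {s.pos: (s.base1, s.base2) for s in sites}

    def single_model() -> AlleleModel:
        cols = _columns_of(fragments, fragments.keys())
        return AlleleModel(
            sample=sample, gene=gene,
            alleles=[_consensus(cols, ref_length, iupac_at=single_iupac)],
            polymorphic_sites=list(sites), warnings=notes,
        )

    if len(sites) < 2:
        return single_model()

    # parity graph: node = fragment covering >= 1 supported site
    side_of: dict[str, dict[int, str]] = defaultdict(dict)  # fragment -> site pos -> base
    touching: dict[int, list[str]] = defaultdict(list)
    site_bases = {s.pos: (s.base1, s.base2) for s in sites}
    for fid, frag in fragments.items():
        for pos, (b1, b2) in site_bases.items():
            b = frag.get(pos)
            if b == b1 or b == b2:
                side_of[fid][pos] = b
                touching[pos].append(fid)

    adj: dict[str, list[tuple[str, int]]] = defaultdict(list)  # parity 0 same, 1 opposite
    for pos, fids in touching.items():
        b1, _ = site_bases[pos]
        anchor = fids[0]
        for other in fids[1:]:
            parity = 0 if side_of[anchor][pos] == side_of[other][pos] else 1
            adj[anchor].append((other, parity))
            adj[other].append((anchor, parity))

    color: dict[str, int] = {}
    for start in sorted(side_of):
        if start in color:
            continue
        # orient the component: at its lowest-position supported site, the
        # lexicographically smaller base goes to allele 0 (deterministic)
        comp = []
        color[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            comp.append(u)
            for v, parity in adj[u]:
                want = color[u] ^ parity
                if v not in color:
                    color[v] = want
                    stack.append(v)
                elif color[v] != want:
                    notes.append("inconsistent phasing linkage; single consensus emitted")
                    warnings.warn(notes[-1], stacklevel=2)
                    return single_model()
        anchor_pos = min(p for f in comp for p in side_of[f])
        b1, _ = site_bases[anchor_pos]
        carrier = next(f for f in sorted(comp) if anchor_pos in side_of[f])
        if (side_of[carrier][anchor_pos] == b1) != (color[carrier] == 0):
            for f in comp:
                color[f] ^= 1

    group = {0: set(), 1: set()}
    for fid, c in color.items():
        group[c].add(fid)
    unlinked = set(fragments) - set(color)

    alleles = []
    phased = []
    for g in (0, 1):
        ids = group[g] | unlinked  # unlinked fragments merge with all alleles
        cols = _columns_of(fragments, ids)
        forced = {}
        for s in sites:
            carriers = group[g] & (set(s.fragments1) | set(s.fragments2))
            if carriers:
                fid = sorted(carriers)[0]
                forced[s.pos] = fragments[fid][s.pos]
        seq = [
            forced[pos] if pos in forced else _call_column(cols.get(pos))
            for pos in range(ref_length)
        ]
        alleles.append("".join(seq))
        phased.append(frozenset(group[g]))

    return AlleleModel(
        sample=sample, gene=gene, alleles=alleles,
        polymorphic_sites=list(sites), phased_fragments=phased, warnings=notes,
    )


def assemble_gene_models(
    records: Sequence[AlignedRead],
    ref_length: int,
    sample: str = "",
    gene: str = "",
    min_fragments: int = 2,
) -> AlleleModel:
    """Full pipeline for one (sample, gene): fragments -> supported
    polymorphic sites -> phased allele model(s)."""
    frags = fragments_from_alignments(records)
    sites, _ = detect_supported_polymorphisms(frags, min_fragments=min_fragments)
    return phase_alleles(frags, sites, ref_length, sample=sample, gene=gene)
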