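# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the pipeline. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic-data generator (`simdata`)

### Model

Gene trees are drawn per locus under the multispecies coalescent on a
user-supplied ultrametric species tree (msprime backend). Time is
measured in **coalescent units** (2N generations of the reference
population): internally every population is given size 0.5·s, where s is
its relative size, so one unit of simulated time equals one coalescent
unit, and a mutation rate "per site per coalescent unit" can be passed to
the mutation engine unchanged.

*Introgression* is modelled as discrete pulses, not continuous migration:
at the event time each lineage sampled in the recipient population
derives from the donor with probability γ (one mass-migration decision
per lineage). This matches the "secondary gene flow" framing the D
statistic is designed to detect; realized migrant-lineage counts are
recorded in the truth object.

*Mutations* follow an effectively infinite-sites regime: a JC69 engine on
a discrete genome, with the rare sites hit more than once simply dropped.
Every retained segregating site therefore traces to exactly one gene-tree
branch, which keeps the truth/genotype bookkeeping exact. There are no
indels: the downstream analyses operate at substitution resolution.

*Genomes.* Loci are concatenated into a single reference contig. The
reference haplotype is the ancestral sequence plus private divergence at
`reference_divergence` (default 0.05 per site, applied outside
segregating sites), emulating a distantly related mapping target — real
mapping used a reference some 20 Myr diverged, and the pipeline must not
depend on the reference agreeing with the ingroup. Each diploid sample
gets two haplotypes with its derived alleles applied.

*Lateral gene transfer.* An LGT event designates a "vertical homolog"
region of the genome, derives a donor copy from it at
`donor_divergence` substitutions per site (default scenarios use 0.15,
the scale of inter-tribe divergence for the C4 gene copies), and appends
that copy — optionally only a sub-span, to model a truncated pseudogene —
to the genomes of the recipient samples only. Reads from appended copies
are emitted unmapped in the truth SAM, since the mapping reference does
not contain them; they are detected from the FASTQ by panel assignment,
exactly as in the real workflow.

*Reads.* Fragments are placed uniformly within each genome segment
(core genome and appended copies, in proportion to length), insert sizes
are normal truncated below at the read length, and each base substitutes
independently at `error_rate`. Qualities are flat Q30 by default, which
passes the Q20 quality pre-filter by construction; a `tail15` mode writes
a Q15 3′ tail to exercise trimming. Herbarium-style fragment-size
degradation is *not* modelled — `insert_mean`/`insert_sd` are exposed
instead of guessing a degradation law.

A single seed drives named child generators per stage (genealogies,
mutations, genomes, reads), so a fixed seed yields byte-identical
FASTQ/SAM/truth output and stages can be re-run independently.

### What passing tests do and do not show

The generator reproduces the *statistical structure* the analyses assume
(ILS, pulses, LGT, shallow Poisson-like coverage, uniform errors) but not
real-data pathologies: no mapping bias or mapping error, no PCR
duplicates, no indels, no recombination within loci, no base-composition
or quality heterogeneity. Calibration results bound what the method can
do under its own assumptions, not under violations of them.

## 2. Genotyping and filters (`genotyping`)

Pileups are built from primary, mapped, proper-pair records only
(everything else is counted and skipped); overlapping mate bases each
count toward depth — no overlap clipping rule is applied, and depth
thresholds must be read accordingly. Genomewide coverage per sample is
total aligned bases over reference length.

SNP discovery is reference-free: a site is a raw SNP when ≥2 distinct
bases each have ≥2 supporting reads summed across samples (ties between
bases break lexicographically A<C<G<T everywhere in the package).
Genotypes are **fixed calls** — at shallow coverage genotype likelihoods
are uninformative, so the field practice for skimming data is followed:
one observed base → homozygote; two → IUPAC heterozygote (a
`min_het_reads` knob, default 1, is exposed); more than two → missing.

The filter cascade, in order:

1. **Per-sample 2.5× rule** (strict >): a cell whose depth exceeds
   2.5× *that sample's own* genomewide mean becomes missing. The
   per-sample reading is used because per-sample means are what a
   coverage table reports; the multiplier is exposed.
2. **Missing-data threshold** (strict >): sites above `max_missing`
   missing fraction are dropped. Presets 0.5 (phylogenetic set) and 0.1
   (structure set). A site at exactly 50% missing is retained.
3. **Duplicated-region flag**: SNPs with depth >5 in ≥50% of samples are
   flagged — the signature of regions duplicated relative to the mapping
   reference collapsing onto one position.

The cascade is idempotent. Known, deliberate bias: at low coverage the
second allele of a heterozygote is often unsampled, so heterozygosity is
underestimated. The missed allele is a fair draw of the two — the
acceptance suite demonstrates this with genotyping at *known* truth
positions, because conditioning on SNP *discovery* (the derived allele
needing ≥2 reads) enriches the surviving calls for the derived allele
and would masquerade as a bias of the caller.

Read resampling to equal base counts draws read pairs without
replacement until the next pair would exceed the target (the lowest
per-sample total among non-exempt samples); exempt samples pass through
complete. Output base counts never exceed the target and are within one
pair of it unless the stopping rule bites earlier.

## 3. ABBA–BABA tests (`dstat`)

Sites enter the count when all four quartet members are called, the
outgroup is homozygous (its allele defines the ancestral state; a
heterozygous outgroup cannot), and the quartet is biallelic. Two modes
handle ingroup heterozygotes:

- `sampled` (default): one allele drawn uniformly per heterozygous call,
  seeded — emulating pattern counting from single reads at low coverage;
- `majority`: fixed calls only; a diploid heterozygote has no majority
  base, so such sites are skipped.

Blocks are consecutive runs of 500 counted-or-skipped SNP positions in
matrix order (physical spans are unavailable when sites are sparse
against a distant reference), so D — though not its SE — is invariant to
the block size. The jackknife deletes one non-empty block at a time and
recomputes D on the pooled remainder; SE, Z and the two-sided normal p
follow the standard delete-one formula. Degenerate cases: fewer than two
non-empty blocks disable the jackknife (flagged, not fatal); identical
delete-one estimates give Z = ±∞ with a warning (Z = 0 when D = 0).
Bonferroni m defaults to the invocation batch size and is otherwise the
caller's choice.

The published Z values for this statistic are reproduced only
qualitatively (sign and significance): the original jackknife block
scheme is unpublished, and Z depends on it. D from published counts is
reproduced exactly.

## 4. Read assignment for lateral gene transfer (`lgtassign`)

The four-step annotation: panel → homology screen → per-read placement →
presence summary.

The screen aligns each read (both strands) semi-globally into each
ungapped panel sequence with edlib; identity is matches over alignment
columns, and a candidate needs ≥50 bp of target span at ≥90% identity
(discovery default; the strict 0.99 setting reproduces a 50 bp/99%
screen). A consequence of semi-global alignment: reads overhanging the
panel segment ends pay for their overhang and can drop below threshold —
conservative, and irrelevant for reads within the segment. Lowering the
identity threshold never removes a candidate.

Placement threads the read into the panel alignment via its best hit and
computes p-distances to every panel sequence over ≥50 overlapping
columns. A neighbor-joining tree of panel-plus-read is then built and the
read is assigned to the label of the smallest labeled clade it nests in,
subject to three conservative gates: (i) the distance margin between the
two closest lineages must reach ε = 0.005, else the read is ambiguous;
(ii) a read attaching *sister to* a clade (rather than inside it) is
accepted only if its pendant branch is shorter than twice the clade
depth (for a single-sequence clade, that sequence's own pendant branch
serves as the depth scale); (iii) the tree assignment must agree with
the nearest-lineage assignment. Mates of a pair are placed independently
and both demoted to unassigned on conflict. NJ on p-distances was chosen
because no per-read inference method is canonical here, it is
deterministic and fast, and lineage recovery on synthetic LGT validates
it: the whole stage uses no randomness.

Presence per (sample, lineage): each read counts toward the exon
partition its span overlaps most; a copy is *present* at ≥`min_reads`
total (default 1 — genuinely shallow data), *truncated* when one
partition reaches the threshold while another has no reads at all, and
*absent* otherwise.

## 5. Allele models (`alleles`)

"Independent reads" means distinct sequenced fragments — mates of a pair
count once; a position where mates disagree is dropped from the
fragment. A second gene model requires at least two polymorphic sites,
each with exactly two bases carried by ≥2 fragments (sites where three
bases clear the bar are flagged and excluded). Phasing two-colors the
fragment graph (same base at a shared supported site → same haplotype;
different → opposite); components are oriented deterministically (at the
component's lowest supported site, the lexicographically smaller base
goes to allele 0). Fragments touching no supported site merge into both
alleles. An odd cycle — inconsistent linkage — falls back to the single
consensus with a warning rather than inventing a third allele, matching
the diploid model (the known polyploid accession was excluded upstream in
the original workflow, and >2-allele phasing is out of scope). Consensus
at unsupported columns is the majority base, ties becoming IUPAC codes;
the IUPAC merge of the two alleles equals the single-allele consensus.

## 6. Population summaries (`popphylo`)

Evanno's ΔK uses the original definitions: L′(K) = mean lnL(K) − mean
lnL(K−1), |L″(K)| = |L′(K+1) − L′(K)|, ΔK = |L″(K)|/sd(lnL(K)) with the
sample SD over ≥2 runs per K over a contiguous K range; sd = 0 yields an
∞ sentinel with a warning. The clustering MCMC itself is not
re-implemented — the module ingests any (K, run, lnL) table — and label
alignment across runs is a greedy correlation matching, not a full
label-switching search. The method reports the full table and the argmax;
choosing between ΔK's maximum and the likelihood plateau remains the
analyst's judgment, as it is in practice.

Heterozygosity is heterozygous calls over called sites per sample —
comparable *between* samples at similar depth, biased downward in
absolute terms (see §2).

p-distances over IUPAC sequences ignore columns with N or gaps; equal
codes score 0, codes with intersecting base sets 0.5, disjoint sets 1.
The half-mismatch rule shifts distances, not topologies, and is a
package decision (full likelihood treatment of ambiguity belongs to ML
tools, which are out of scope). Neighbor joining is the classical Q
criterion with two determinism guarantees the tests rely on:
ties break lexicographically on clade names, and negative branch lengths
clamp to zero; output is invariant to input order and cross-checked
against an independent NJ implementation.

## 7. Problem sizes used in the test suite

Calibration uses 500 loci × 300 bp, one diploid sample per tip of a
4-tip tree (splits at 1, 2, 3 coalescent units), μ = 0.01/site/coalescent
unit, 8× error-free coverage — chosen so the no-flow null and a γ = 0.3
pulse are cleanly separable (~10³ informative sites) while a 20-seed
replicate set runs in about a minute. Genotype-recovery fixtures use
150–800 loci at 10× and 1×; LGT recovery uses a 6 kb genome, two 1.5 kb
gene copies at 15% donor divergence (one truncated to 700 bp) and 2×
coverage. These sizes are the package's own scaled study conditions; the
statistical structure, not the genome size, is what the assertions test.

## 8. Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally, 1-based on VCF/SAM write.
All tie-breaks are lexicographic (base order A<C<G<T, then name order).
Every sampling step takes an explicit seed; assignment and phasing are
RNG-free. Zero informative sites is an error for D; an empty SAM warns
and yields zero coverage; an all-missing sample is omitted from
heterozygosity with a warning; `n_loci = 0` yields empty truth.

## 9. Known limitations

- No genotype likelihoods/posteriors — fixed calls are the point, and
  their homozygosity bias is documented, not corrected.
- No read mapping: alignments come from the simulator or external SAM.
- No f4/f3/graph statistics; no ML/Bayesian trees; no molecular dating.
- Diploid-only phasing; polyploids must be excluded by the caller.
- The simulator's error and fragment models are deliberately simple
  (uniform substitutions, normal inserts, flat qualities).
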