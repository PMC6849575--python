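# skimflow

Population genomics from **genome skimming** — shallow (≈0.7–4.5×)
whole-genome sequencing of the kind used for herbarium and other
low-input plant material. The package re-implements, as a tested and
reusable pipeline, the analysis stack needed to ask two questions about a
polymorphic species complex such as the C4/non-C4 grass *Alloteropsis
semialata*:

1. **Has there been secondary gene flow between diverged gene pools**, or
   is phylogenetic discordance explained by incomplete lineage sorting
   alone? (ABBA–BABA tests on genome-wide SNPs.)
2. **Which accessions carry laterally acquired copies of C4 genes**
   (*ppc*, *pck*) donated by distantly related grasses, and are those
   copies intact or truncated? (Phylogenetic read assignment against a
   labeled gene-lineage panel.)

Because coverage is far too low for likelihood-based genotyping, the
pipeline uses *fixed* genotype calls with a bespoke filter cascade, and
every inference step is calibrated against a built-in coalescent
simulator that emits reads with machine-readable truth.

## What is inside

| module | contents |
|---|---|
| `skimflow.simdata` | multispecies-coalescent simulator (msprime) with discrete introgression pulses, lateral-gene-transfer donors, diploid genomes, low-coverage paired reads (FASTQ/SAM) and truth records |
| `skimflow.genotyping` | pileups from proper-pair alignments, reference-free SNP calls, IUPAC heterozygote coding, the 2.5×-coverage / >2-allele / missing-data filters, duplicated-region flag, equal-bases read resampling, VCF + alignment export |
| `skimflow.dstat` | ABBA/BABA site-pattern counting, Patterson's D, delete-one block jackknife (Z, p), Bonferroni correction |
| `skimflow.lgtassign` | homology screen (edlib, both strands), per-read neighbor-joining placement into a labeled panel, presence/absence/truncation reports |
| `skimflow.alleles` | per-gene allele models: ≥2-sites/≥2-fragments support rule, fragment phasing by graph two-coloring, IUPAC consensus |
| `skimflow.popphylo` | Evanno ΔK from cluster-run likelihood tables, per-sample heterozygosity, IUPAC-aware p-distances, deterministic neighbor joining |

## The core statistic

For an ordered quartet laid out `(Outgroup,(P3,(P2,P1)))`, every biallelic
site where the outgroup carries the ancestral allele A and the derived
allele is B contributes to one of two discordant patterns:

```
ABBA : P1=A  P2=B  P3=B        BABA : P1=B  P2=A  P3=B
```

Incomplete lineage sorting produces both at equal expected frequency;
gene flow between P3 and one of P1/P2 breaks the symmetry. Patterson's D,

```
D = (nABBA − nBABA) / (nABBA + nBABA),
```

is tested with a delete-one block jackknife over blocks of consecutive
SNPs: with m blocks and delete-one estimates D(i),

```
SE = sqrt( (m−1)/m · Σi (D(i) − mean D(i))² ),   Z = D / SE,
```

and p is the two-sided normal tail, Bonferroni-corrected across tests.

## Worked example

Simulate a quartet with substantial incomplete lineage sorting and a 30%
introgression pulse from P2 into P3, genotype it from the reads, and test:

```bash
cat > sim.yaml <<'YAML'
n_loci: 50
locus_length: 300
mutation_rate: 0.01
coverage: 6.0
read_length: 100
insert_mean: 220
insert_sd: 30
seed: 3
introgression_events:
  - {donor: P2, recipient: P3, time: 0.1, proportion: 0.3}
YAML

skimflow simulate --config sim.yaml --out simout --seed 3
skimflow genotype simout/{P1,P2,P3,O}.sam --reference simout/reference.fasta --out raw.vcf
skimflow filter raw.vcf simout/{P1,P2,P3,O}.sam --reference simout/reference.fasta \
    --max-missing 0.5 --out filt.vcf
skimflow dstat filt.vcf --quartet P1,P2,P3,O --block 200 --seed 1
```

which prints (this run: 1910 segregating sites, 1727 raw SNPs):

```
Outgroup  P3  P2  P1  nABBA  nBABA  D      Z      p      conclusion
O         P3  P2  P1  40     26     0.212  0.756  0.450  no significant asymmetry (ILS-compatible)
```

The pulse inflates ABBA over BABA (40 vs 26) and D is positive, but at 50
loci the jackknife correctly refuses to call it significant — power
arrives with genome-scale input (the acceptance suite runs the same
pipeline at 500 loci, where a 30% pulse gives Z > 3 in ≥18/20 replicates
while the no-flow null stays at |Z| < 2). The per-sample heterozygosity
of the same matrix shows the recipient's mixed ancestry:

```
skimflow het filt.vcf
P1  0.092
P2  0.066
P3  0.193   <- introgressed sample: heterozygous at inter-clade differences
O   0.078
```

The same pattern — individuals assigned to multiple genetic clusters
having the highest heterozygosity — is what flags admixed accessions in
real data. Cluster-number selection from clustering-run likelihoods works
on a plain TSV:

```
skimflow evanno runs.tsv      # columns: K, run, lnL
...
best K by deltaK: 2
```

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
what the simulator does and does not emulate, and the numerical and
design choices in detail.
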