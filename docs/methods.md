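# Methods

This note records the models, conventions and numerical choices behind
`panhap`, and what the synthetic-data generators do and do not emulate.

## Pan-genome classification

Families are classified by occupancy (number of genomes with ≥ 1 member):
occupancy *N* → core, [softcore_min, *N*−1] → softcore, [2, softcore_min−1]
→ dispensable, 1 → private. Classes are mutually exclusive and partition
the families, so the four percentages sum to 100 up to rounding (reported
to 2 decimals). `softcore_min` defaults to *N*−1 ("all but one genome") and
is configurable down to ⌈0.9·*N*⌉-style thresholds for larger panels.
Singletons — genes absent from every family — are counted by set difference
against per-genome gene universes, which must be disjoint across genomes.

## Rarefaction and growth models

For each subset size *k* = 1..*N* the simulation draws `reps` (default
1000) uniform *k*-subsets of genomes, independently, so the same subset may
recur — standard rarefaction practice. When C(*N*,*k*) ≤ `reps` all subsets
are enumerated exactly once instead and the size is flagged exhaustive;
sampled and exhaustive medians therefore agree exactly on small panels.
Pan is the count of families present in ≥ 1 subset genome, core the count
present in all; within any nested chain pan is non-decreasing and core
non-increasing.

Medians are fitted by least squares with:

* pan: P(k) = A_p·k^{B_p} + C_p (Tettelin-style power law),
* core: C(k) = A_c·e^{−B_c·k} + C_c (exponential decay).

The model forms are a design choice — the motivating study names only its
fitting routine — and both are isolated behind the fit function.
Initialization is deterministic: A from the median range, B from the median
log–log slope (pan) or 0.5 (core), C from the last median, followed by 10
deterministically jittered restarts (fixed internal RNG); the best residual
sum of squares wins and non-convergence is flagged with the best attempt
retained. Zero-noise inputs recover their generating parameters to 1e-6
relative error, and the returned RSS dominates a 50×50×50 grid search on
random instances.

The plateau is the smallest *k* ≥ 2 such that every subsequent step grows
the median pan by less than `rel_threshold` (default 0.005, i.e. < 0.5%).
Requiring *all* subsequent steps, not just one, prevents spurious early
plateaus on noisy medians. A zero median is an error (the relative
increment is undefined).

## Variant effects

Coordinates: external formats keep native conventions (VCF and GFF3 are
1-based closed); internal arithmetic converts at the I/O boundary only.
Multi-allelic VCF sites are split into biallelic records; genotype calls
involving a different alternate allele become missing for the split record,
and `./.` is always missing, never reference. Malformed genotypes are
skipped record-by-record with a warning and counted in the load report
(a line-level genotype-grammar screen runs before htslib parsing, which
would otherwise abort the whole stream). QUAL is stored as float32 by
htslib and rounded back to 4 decimals on read.

Filtering retains records with qual ≥ 20 and depth ≥ 50 (both inclusive).
Record depth is the sum of available per-sample depths; a record with no
depth anywhere fails the depth rule. Size classes: SNP (|ref| = |alt| = 1),
InDel (< 50 bp), SV (≥ 50 bp), with SV length end − pos + 1 under the
closed-interval convention (or the inserted length for INS).

Region assignment tests exon membership first, so "exonic" includes UTR
positions and exonic subclass percentages include UTR variants. Coding SNPs
translate the affected codon with ref and alt alleles under the standard
nuclear code, reverse-complemented on the minus strand: same amino acid →
synonymous, stop gained → nonsense, else missense (stop-loss is reported as
missense). CDS InDels are frameshift when size mod 3 ≠ 0, else inframe.
Splice windows follow common annotation practice: donor/acceptor are the
first/last two intronic bases in transcription order, splice_region is
within 8 intronic or 3 exonic bases of a junction. InDels are classed by
their leftmost affected base (the base after the shared VCF anchor) and
flagged when their span crosses an exon–intron boundary. A variant
overlapping several genes takes the most severe consequence (nonsense >
frameshift > missense > inframe > splice donor/acceptor > synonymous > UTR
> splice_region > intronic), ties broken by the smaller gene id. Genes
whose CDS length is not a multiple of three are flagged at load time and
excluded from coding-effect calls. A REF allele disagreeing with the genome
sequence is an error naming the position.

## SV merging

Two calls link when they share chromosome, type and strands (each
requirement can be relaxed by flag) and both |Δstart| ≤ `max_dist` and
|Δend| ≤ `max_dist` (default 1000 bp, the conventional merge distance;
insertions compare insertion point and inserted length, translocations
require both loci to match). Clusters are the single-linkage closure, so a
chain can span more than `max_dist` end to end — the documented trade-off
of chain-style merging. Records shorter than `min_len` (default 50 bp) are
dropped first. The representative is the medoid (minimum summed breakpoint
distance, ties by coordinates then sample), and the output ordering is
canonical, making the merge invariant to sample and record order and
idempotent on its own output.

## Duncan's multiple range test and superior haplotypes

Haplotype enumeration uses the gene body region with no flank by default
(flanks are caller-controlled via the region argument). Accessions with any
heterozygous call in the region are excluded first (reason `het`), then
those with missing calls (`missing`); labels H1, H2, … follow descending
carrier frequency with ties broken by first occurrence.

The test computes one-way ANOVA MSE and error df, sorts means descending,
and uses the least significant range LSR(p) = q(1−α_p, p, df)·√(MSE/n_h)
for a span of *p* means, with protection level α_p = 1−(1−α)^(p−1) and n_h
the harmonic mean group size (standard Duncan practice for unequal groups).
Studentized-range quantiles come from numerical evaluation of the
studentized range distribution, not printed tables. The stepwise procedure
tests the widest span first; a span found homogeneous protects all its
sub-spans; maximal homogeneous spans become the letters. Consequences: two
groups share no letter exactly when the protected all-pairs criterion
declares them different, and under the null the probability of any letter
separation equals the widest span's protection level (verified by Monte
Carlo). With two groups the procedure reduces to a two-sample comparison
with critical value q(2, df, α)/√2 — the two-sided t critical value. Zero
within-group variance everywhere is an error: the statistic is undefined.

A haplotype qualifies for phenotype comparison with ≥ `min_n` (default 5)
phenotyped carriers. The superior call formalizes "highest trait mean in a
distinct Duncan group": the top-mean qualifying haplotype is superior only
when its letter set is disjoint from the bottom-mean qualifying
haplotype's; otherwise no superior haplotype is declared.

## KASP scoring

A marker is polymorphic when ≥ 1 non-donor cultivar's homozygous call
differs from the donor's homozygous call; H and NA calls are excluded from
the comparison but counted in the report, and markers with an H/NA donor
call or all-NA calls are flagged uninformative. A cultivar carries the
superior allele only when homozygous for the allele linked to the superior
haplotype — the conservative reading of homozygous allele reports such as
"C/C". Allele letters are matrix-local (A/B per marker).

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (spec, seed); a single seed feeds named
streams (CRC32 of the stream name mixed into the seed) so stages regenerate
independently. Defaults mirror the motivating study's published conditions:
the pan-genome spec defaults to 17 genomes with class counts
17483/2656/13986/220; the haplotype spec plants the published extreme
100-seed-weight means 29.84 g and 14.66 g with 1 g homoscedastic Gaussian
noise (about 100 accessions split between the extreme haplotypes — chosen
as a realistic panel slice, since per-haplotype carrier counts for the full
3171-accession panel are not published); the KASP generator produces 23
markers of which 20 are polymorphic against the donor.

Deliberate simplifications: dispensable occupancy is uniform over its range
unless specified; per-cell gene counts are 1; haplotype effects are
additive constants with homoscedastic noise (the simplest structure under
which Duncan grouping is well-posed); SV clusters are separable by
construction (truncated jitter, wide centroid gaps) so merge correctness is
decidable; toy genomes have no repeats, no overlapping genes, no
alternative transcripts, and no linkage disequilibrium between SNP sites.
Passing tests therefore demonstrate correctness of the algorithms under
clean class structure, not robustness to real-data artefacts such as
mis-annotated gene models, reference bias, or correlated noise.

## Problem sizes and known limitations

The test suite runs the property scales the analyses are specified at
(1000 random matrices for classification identities, exhaustive rarefaction
agreement on 4–6 genome panels, 500 labelled variants for classifier
agreement, 50 planted SV call sets, 2000 Monte-Carlo replicates for Duncan
calibration, 200 planted haplotype datasets); the acceptance script runs
the published-scale inputs (34,345 families, 2.47 M SNP counts, 280,195 SV
records). The real 17-genome family matrix, the full variant catalogues and
the 3171-accession haplotype panel are external datasets; quantities that
depend on them (e.g. the observed ~11-genome plateau of the real matrix)
are out of desk scope and are replaced by planted-truth properties.
One published rounding quirk is surfaced by recomputation: 17483/34345 =
50.904%, which this package reports as 50.90 where the source figure prints
50.91. Gene counts are per primary transcript; MNPs are classified at their
leftmost affected base; the merge distance and any minimum-support
threshold of the original SV merge are not published, so the defaults here
(1 kb, no minimum support) are explicit flags.
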