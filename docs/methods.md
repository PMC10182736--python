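# Methods

This note documents the models implemented in `genebirth`, their
assumptions, the tunable parameters and their defaults, what the
synthetic-data generators do and do not emulate, and the numerical and
design choices made where the procedure was genuinely open.

## Species tree and branch labels

A rooted species tree (newick, branch lengths in substitutions per site)
is annotated with labels N0..Nk on every node of the path from the
reference species' terminal branch (N0) to the root (Nk). A tip may
stand for a group of species ("multi-species terminal nodes"); presence
of any one member species counts the tip as present. The birth branch of
a gene family is the label of the most recent common ancestor of the
species with members — equivalently, the most distant species in the
family dates the birth. Families whose MRCA is the root itself span the
deepest split and are treated as clade-unrestricted (conserved
candidates), so in-tree births occur on N0..Nk−1.

Two bundled tree presets exist for simulation: an 11-tip yeast-like tree
(reference path N0..N5, reference terminal branch 0.043 substitutions per
site) and a 16-tip fly-like tree (N0..N6, terminal branch 0.011) whose
*D. willistoni* tip carries a second species to exercise the
multi-species-tip rule. Topologies and branch lengths are plausible for
the clades they imitate but are not estimates of any real tree.

## Classification

Reference-species genes are partitioned into six classes: putative de
novo, duplicated, de novo + duplicated, conserved, WGD-excluded, and
removed-for-outgroup-homology. The order of application is:

1. genes on the user-supplied whole-genome-duplication list are excluded
   first (WGD exclusion is input-driven, never inferred);
2. clade-restricted families are de novo candidates at their MRCA branch;
   candidates with homology hits at E < `e_max` (default 0.001) in at
   least `min_outgroup_species` (default 2) distinct outgroup species are
   removed (likely ancient genes repeatedly lost within the clade);
3. remaining candidates listed in a supported duplication record are
   de novo + duplicated (dated at the de novo birth); the rest are
   putative de novo;
4. in unrestricted families, genes listed in a duplication record are
   duplicated, dated at the most recent event listing them (both sides of
   a duplication are paralogous and both are counted as duplicated
   proteins); everything else is conserved.

Duplication records are accepted at reconciliation support ≥ `support_min`
(default 0.5 — a conventional majority threshold; the source tables do
not dictate one). Events and proteins are accounted separately: one de
novo event per family that retains at least one candidate, one
duplication event per supported record, so per-branch protein counts are
always ≥ event counts. Duplication events whose descendants exclude the
reference species are kept as branch events but flagged
(`reference_less`), since a reference-centric table cannot attribute
proteins to them.

Normalized birth rates divide event counts by 100 × branch length, i.e.
events per amino-acid substitutions per 100 sites; a zero-length branch
with events is an error rather than an infinite rate.

## Normalized PN/PS

The mutation matrix holds the relative frequencies of the 12
single-nucleotide substitution types, estimated from intronic SNPs that
overlap no exon (ref→alt orientation as recorded; a `symmetrize` option
averages strand-complementary entries, and which mode was used is
recorded in output metadata). The neutral expectation for a CDS set
enumerates, for every codon occurrence, its nine single-nucleotide
mutants: amino-acid-changing mutants add their matrix weight to EN,
silent ones to ES. Stop-gaining mutants are excluded from both by
default (nonsense ≠ missense; the switch `count_nonsense_as_nonsyn`
folds them into EN). Observed PN and PS classify each SNP independently
against the reference codon — two SNPs in one codon are scored
separately — after discarding SNPs below the minor-allele-frequency
cutoff (`maf_min`; 0.05 for the yeast-style profile, 0 for the fly-style
profile). Groups pool counts, not per-gene ratios, so genes with PS = 0
contribute without producing undefined per-gene values; a pooled group
with PS = 0 or ES = 0 is flagged undefined rather than given a number.
Subsampling SDs repeat the pooled computation on `reps` (default 1,000)
seeded draws of ⌈n/3⌉ genes without replacement.

Age classes are pooled for SNP paucity: {N0}, {N1–N4}, {N5} in the
yeast-style scheme and {N0}, {N1–N2}, {N3–N4}, {N5}, {N6} in the
fly-style scheme, plus a conserved group; genes born de novo that later
duplicated are excluded from all property comparisons.

## Amino-acid substitution model

Observed pair counts come from alignment columns where both residues are
standard amino acids and differ; gap/ambiguous columns are skipped
(selenocysteine unsupported). The expected weight of an ordered change
aa_i→aa_j sums f(c1)·m(base change) over its single-nucleotide codon
routes; the unordered pair adds both directions. The table is restricted
to pairs that are single-nucleotide reachable AND observed in the focal
group (the restriction applies to the unordered pair), then scaled so
expected totals equal observed totals. Codon frequencies are computed
separately per group to absorb compositional differences. log2(O/E) is
reported per pair and per residue-class pair, aggregating counts before
the ratio; classes default to acidic {D,E}, basic {K,R,H}, polar
{S,T,N,Q,C,Y}, nonpolar {A,V,L,I,P,F,M,W,G} (Cys/Gly placements vary in
the literature; the scheme used is recorded in output metadata and is
configurable).

Direction of change is inferred from three-species alignments by
parsimony: a column counts only when exactly two species share a residue
and the reference is one of them; the shared residue is ancestral and
the differing sister carries the derived state on its own branch.
Columns with a gap in any of the three species are excluded. Per-pair
enrichment between a focal and a background group uses two-sided Fisher
exact tests (one-sided available) with Benjamini–Hochberg correction
(Bonferroni available) — the correction method was an open choice and is
configurable.

## Sequence properties

Isoelectric point solves net charge = 0 by bisection on pH ∈ (0, 14) to
|charge| < 1e−4, with Henderson–Hasselbalch terms for the termini and
D, E, C, Y, K, R, H side chains. The default pK table is the EMBOSS set
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1); the exact table behind published pI values is often unstated,
so the table is configurable and recorded in output metadata. Class
fractions exclude unclassifiable residues from the denominator. The
intron-derived control set translates introns either through the ORF rule
(NTG→stop, ≥ 10 aa; default, consistent with the ORF definition used
elsewhere in the pipeline) or as a fixed frame-1 translation with stops
removed (`frame1`); the policy is exposed rather than guessed silently.
Group comparisons use two-sided Mann–Whitney–Wilcoxon tests, exact for
small tie-free samples and normal-approximated with tie correction
otherwise; medians use the midpoint convention for even group sizes.

## MUM synteny blocks

The MUM finder builds a suffix array (prefix doubling) and Kasai LCP
array over the two genomes joined by a sentinel. A cross-genome adjacent
suffix pair whose common prefix is at least `min_len` and strictly longer
than both flanking LCP values is unique in the combined text — hence
unique in each genome — and left-maximality requires differing preceding
characters. `N` bases are encoded as per-position unique symbols so they
never match. Reverse-orientation MUMs are computed against the reverse
complement of genome B (coordinates reported on B's forward strand) and
are never clustered with forward MUMs. Defaults: `min_len` 20 (an
anchor-length convention for same-genus genome comparisons; recorded in
output metadata), cluster gap `max_gap` 100 bases. Clustering chains
MUMs sorted by genome-A position when they are parallel (same
orientation), consecutive (consistent order in both genomes; an order
inversion always splits) and neighboring (gap ≤ `max_gap` in **both**
genomes — the stricter, order-consistent reading of a single-threshold
rule). Gene-level synteny is overlap of the gene interval with any block
span (≥ 1 bp by default; a minimum-fraction option exists).

## Synthetic data

A single top-level seed deterministically derives one child stream per
generator (CRC-based, so regeneration of any one module is independent
and byte-identical across processes).

*Gene histories.* Births are Poisson per reference-path branch (de novo
and duplication rates default 2 events/branch, de novo-then-duplicated
0.25). A de novo gene is present in exactly the species descending from
its birth branch, minus lineages lost independently with `loss_prob`
(the reference is never lost, otherwise the family would be
unobservable). Duplications are planted inside all-species conserved
families and emit duplication records at the true branch with support
1.0. A configurable fraction (default 5%) of de novo families are
"contaminants" given hits in two outgroup species at E = 1e−10 to
exercise the homology filter; conserved families also receive outgroup
hits. The generator does not emulate orthology-inference errors — family
membership is exact — so recovery tests measure the classification
logic, not robustness to clustering noise.

*CDS and SNPs.* Coding sequences draw codons from the configured codon
usage (default: an average-proteome amino-acid composition spread
uniformly over synonymous codons) between a start ATG and a stop. A CDS
SNP picks a codon occurrence uniformly, accepts it with probability
proportional to the codon's total mutability, picks one of the nine
mutants with probability proportional to the matrix, discards
stop-gaining mutants, and accepts nonsynonymous mutants with probability
f (the purifying factor; synonymous with probability 1) — so the
realized neutral route distribution is exactly f(codon)·m(change) and
the normalized PN/PS of the output converges to f. Intronic SNP types
are drawn directly from the matrix, making the downstream matrix
estimate consistent. Genes sit on their own contigs on both strands so
coordinate/strand mapping is exercised; minor allele frequencies are
uniform on (0, 0.5) and independent of SNP type, so MAF filtering does
not bias recovery. Default scale: 500 genes × 300 codons, 10,000 CDS and
10,000 intronic SNPs — large enough that recovery error is a few
percent, small enough to regenerate in about a second.

*Protein families.* Pairs (reference + sister) or triples (reference +
two independently evolved sisters) under a site-independent,
strictly first-order codon model: each codon experiences at most one
candidate substitution per branch, with probability d·W(c)/W̄ (W(c) the
codon's total mutability, W̄ its average), the mutant drawn from the
matrix, stop-gaining events discarded, and basic→acidic amino-acid
changes accepted with relative weight s (the charge-shift factor;
s = 1 is neutral). First-order evolution is deliberate: the neutral
expectation describes single-nucleotide changes, and multi-hit codons
would fold a model-mismatch term into what should be a calibration test
(with Poisson multi-hit at realistic divergence the acidic/basic class
deviates by ≈ −0.2 log2 units for reasons unrelated to the statistic).
No indels are simulated, so alignments are trivially columnwise; gap
handling is covered by hand-written fixtures instead. Consequently the
generator says nothing about alignment error on real data.

*Genome pairs.* Genome A concatenates random conserved blocks; genome B
interleaves the same blocks (optionally point-mutated at a configured
rate) with unrelated random insertions. True block intervals are
recorded. Recovered MUMs can chance-extend a few bases past a block
junction (each extra base matches with probability 1/4), which tests
tolerate explicitly.

## Calibration scale and statistical checks

Stochastic recovery tests run at fixed seeds with a priori tolerances:
purifying-factor recovery at the default 500 × 300/10,000-SNP scale
(tolerances ±0.05 at f = 0.1 and 0.3, ±0.10 at f = 1.0); the neutral
log2(O/E) calibration pools three replicates of ≈ 5,000 amino-acid
changes and requires every class-pair value within ±0.2 of 0 — pooling
is used because a single 5,000-change draw leaves ≈ 0.12 SD of pure
counting noise on the smallest class pair, which would make a ±0.2 check
a coin-flip-scale test of the random number stream rather than of the
model. The MUM finder and the codon-level neutral expectation are
checked for exact agreement against brute-force oracles (50 random
genome pairs up to 1 kb; all 61 sense codons × 20 random matrices).

## Known limitations

- Orthogroups, duplication records and alignments are consumed as given;
  inference error in those inputs is out of scope and not simulated.
- The GFF3 reader supports only CDS/exon/intron features, and CDS are
  assumed contiguous on their contig when mapping SNPs to codons
  (spliced CDS coordinate arithmetic is not implemented).
- Isoform tie-breaking at equal protein length (lexicographically
  smallest isoform id) is a convention; real annotation pipelines differ.
- The neutral substitution models treat sites independently; context
  effects (e.g. CpG-like hypermutability) and indels are not modelled.
- Branch lengths are taken as given; no rate heterogeneity across
  branches is modelled when normalizing birth rates.
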