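# Methods

`rapidseq` re-creates, at desk scale, the computational core of a rapid
whole-genome sequencing (WGS) pipeline for suspected monogenic disease:
hash-index read mapping, haplotype-based small-variant calling,
ACMG-style variant categorization, and phenotype-driven trio
interpretation, together with a synthetic-data generator and a
concordance evaluator so that every stage can be exercised and scored
without external data. This note records the models, the parameters
that matter, and the choices made where the design was genuinely open.

## Read mapping

**Index.** The reference's forward strand is indexed by every primary
seed (default 21 nt; seeds containing N are skipped). A seed occurring
at more than `max_hits` (16) locations is not stored as a long hit
list; instead the table holds an EXTEND record telling the query to
join additional read bases symmetrically onto the seed (increments of
3 nt per side, cumulative cap 64 nt per side, so the longest extended
seed is 21 + 2.64 = 149 nt) and re-query, iteratively. Groups that are
still too frequent at the cap are marked high-frequency and return no
hits — such seeds carry almost no placement information, and ignoring
them mirrors how production mappers treat uninformative seeds. Keys
are exact strings (extended keys bind the additional bases to an
identifier of the pre-extended seed); no lossy hashing is used, so the
index can be checked verbatim against a naive substring scan.
Occurrences whose extension window would run past a contig end are
dropped from deeper extension levels; reads genuinely anchored there
still map through their other ~40 seeds.

**Mapping.** Seeds are extracted at every even read offset (50%
density). Hits on one diagonal (reference position minus read offset,
in strand-oriented coordinates) merge into seed chains; a chain is
discarded when a chain at least 4x longer overlaps more than half of
its read span. Chains pair across mates under a forward/reverse layout
with an insert inside mean +/- 4 sd; the insert model is fitted from up
to 10,000 pairs in which both mates have a single chain (fallback: the
configured model, default Normal(350, 50)). When one mate fails to
seed, a rescue scan slides the first 24 nt of the expected mate
sequence across the insert window and accepts placements within
Hamming distance 3; each acceptance becomes an alignment candidate.

Each candidate is aligned gaplessly on its diagonal — per-base
match/mismatch scores with the optimal prefix/suffix soft clips found
in one pass over prefix sums — and escalated to full-matrix affine
Smith-Waterman (scores: match +2, mismatch −3, gap open 5, gap extend
1, per-end unclipped bonus 5) when the gapless score falls below 0.9 of
perfect or a clip exceeds 5 nt. Candidates on one contig/orientation
whose reference intervals overlap are collapsed to the best-scoring
one: chains split by an indel land on two diagonals that converge to
the same placement after gapped alignment, and without this
reconciliation the second-best score would sit just under the best and
erase MAPQ precisely at indels.

**MAPQ.** `MAPQ = clamp(round(alpha(L)(S1−S2)) − 2·log2(1+N2), 0, 60)`
with `alpha(L) = 60/L` and `N2` the number of additional candidates
within 2 points of the second-best score; a read with a single
candidate placement gets 60. The coefficient is calibrated so that a
~34-point score margin (about 2.5 mismatches at these scores) reaches
MAPQ 20, the caller's confidence floor; a proportionality constant much
smaller than this would bar every multi-candidate read from calling
regardless of how decisive its margin is. Pair scores subtract a
pairing penalty of one point per sd of insert deviation, capped at 40.
When the chosen alignment covers less than 80% of the read, up to
three supplementary alignments are emitted for read segments the
primary leaves uncovered.

## Duplicates

Pairs sharing both mates' 5'-unclipped positions and orientations form
a duplicate group; the highest pair-score member stays unflagged, ties
break on read id, and flagging is idempotent. Optical duplicates are
not modeled (no tile coordinates exist in the simulation).

## Variant calling

**Regions.** Callable columns have depth >= 4 from primary alignments
with MAPQ >= 20; reads spanning a deletion (CIGAR D) count toward that
depth — otherwise a homozygous deletion contains no callable columns
and can never be detected. Active columns are callable columns where
the non-reference evidence fraction reaches 0.15. Mismatch evidence
comes from confident primaries; indel and long-soft-clip (>= 10 nt)
evidence is collected from *all* mapped, non-duplicate records
including supplementary and low-MAPQ alignments, because reads
spanning a long deletion junction are split between the two junction
sides by mate-side pairing and either side alone can fall below
trigger depth. Active runs are padded by 50 nt (150 nt when indel
evidence is present, wide enough that both junctions of a 263-nt
deletion merge into one region) and merged.

**Assembly.** Full read sequences overlapping the region (soft-clipped
bases carry the insertion evidence), plus unplaced mates anchored in
the region in the orientation implied by the FR layout, are assembled
into a De Bruijn graph over the reference backbone. k is taken from
the schedule {10, 25, 40, 55}, moving to the next k whenever the
backbone repeats a k-mer or the graph is cyclic ("degenerate").
Non-backbone edges seen fewer than 2 times are pruned. All
source-to-sink paths become haplotypes, capped at 128 preferring
higher minimum edge weight; the reference haplotype is always kept. A
region degenerate at every k is skipped (reference haplotype only,
logged).

**Events.** Each haplotype is aligned globally (both ends anchored) to
the region reference; substitutions and indels are read off the CIGAR
and left-normalized with the standard shift-left algorithm, which the
tests check against a brute-force enumeration of equivalent
placements. Indels above 470 nt are not represented — slightly above
the largest events this design is expected to span (a 263-nt deletion
and a 469-nt insertion, both covered by the test suite).

**Likelihoods and genotypes.** P(r|H) uses a three-state (M/I/D)
pair-HMM evaluated with the forward algorithm — the same matrix shape
as Smith-Waterman but summing path probabilities — in linear space
with per-row rescaling. Match emissions come from base quality capped
by MAPQ (`p_err = 10^(−min(Q, MAPQ)/10)`; mismatches emit `p_err/3`);
gap opening follows a PCR-stutter stand-in keyed to the homopolymer
run length at the haplotype position, `10^−(4 − 0.5·min(run, 6))`
(3.2e−4 at run length 1, 0.1 from run 6 up), with constant gap
extension 0.1. The run-length form and constants are a package choice;
they are config-overridable. Reads are trimmed to the active region by
unclipped-coordinate projection before evaluation. Read start is
uniform over haplotype columns and the end is free, so partial overlap
is handled naturally.

Per event `e` at a position, P(r|e) is the maximum P(r|H) over
haplotypes carrying `e` (for the reference allele: haplotypes with no
event at that position). Diplotype candidates are all unordered allele
pairs; a diplotype's per-read likelihood is the even mixture
(P(r|e1)+P(r|e2))/2, multiplied over reads overlapping the position
and combined with a heterozygosity prior (theta = 0.001 split evenly
over non-reference diplotypes) into normalized posteriors. The winner
is emitted with GQ = −10·log10(1 − posterior), capped at 99; QUAL is
the phred-scaled posterior of homozygous reference. Only
event-overlapping reads enter the product: reads elsewhere in the
region carry no information about the site and would only add noise.

## Annotation and interpretation

Consequences are computed from transcript geometry (BED12 models) and
codon translation, most severe across transcripts: intronic +/-1,2 =
splice disruption; acceptor −3..−20 = polypyrimidine tract; intronic
>20 nt from any boundary = deep intronic; exonic within 3 nt of a
splice boundary = exonic splice region; CDS logic distinguishes loss
of initiation, premature stop, stop disruption, frameshift vs in-frame
indels, synonymous vs non-synonymous. Synonymous variants get a crude
cryptic-splice flag (creation of a GT/AG dinucleotide within 3 nt).
Categories: 1 known disease-causing, 5 known benign (known status wins
both ways), 2 for the expected-pathogenic consequence types, 3 for
possibly-pathogenic types (and flagged synonymous), otherwise 4;
variants "common in unaffected individuals" are category 4 at
MAF >= 2%, a threshold this package sets since the category
definitions themselves carry no number. Warehouse MAF = allele count /
(2 x sample count) from a local TSV cohort table.

The interpreter ranks diseases by the number of patient HPO terms they
match (at least one required, ties alphabetical) and filters the trio
by category set, MAF ceiling (strict <, or cohort uniqueness) and
inheritance: de novo requires both parents reference with GQ >= 30
everywhere; recessive is homozygous-with-carrier-parents, X hemizygous
in a male, or a compound heterozygote with at least one allele
inherited from each parent (in trans); dominant is affected-only, so
with unaffected parents dominant candidates must also be de novo;
mitochondrial means the MT contig. Candidate genes are ranked by
presence on the differential, best disease rank, then category.

## Synthetic data

The generator emulates the study conditions at desk scale: a uniform
random reference (default 250 kb, one contig), SNVs at 1e−3/nt and
indels at 1.25e−4/nt (geometric sizes, mean 3, cap 470), genotypes half
het / half hom-alt, 2x101 paired reads with insert ~ Normal(350, 50)
truncated at 202, i.i.d. base errors at 0.2% and a flat Q30 quality
profile (optional linear 3' decay). Events are planted non-overlapping
after left-normalization, with a 12-nt buffer after indels, so each
site carries exactly one well-defined diplotype. No variants are
planted within 400 nt (insert mean + 1 sd) of contig ends: paired-end
coverage of a linear molecule necessarily ramps down over about one
insert length at its ends, an effect that is negligible genome-wide at
chromosome scale but would dominate the error budget of a 250-kb toy
contig. Trio mode simulates the parents independently and transmits
one haplotype from each to the child, plus a configurable number of de
novo SNVs on the maternal-origin haplotype.

What the simulation does *not* model: GC/coverage bias, correlated or
position-dependent sequencing error, optical duplicates, PCR
duplicates (fragment positions collide only by chance), structural
variation beyond simple indels, repeat families at genome scale, and
real gene/phenotype databases. Passing the end-to-end thresholds here
therefore demonstrates the algorithms' correctness under idealized
error and repeat structure, not clinical-grade performance on human
data.

**Concordance.** Calls are decomposed into alleles, left-normalized on
the shared reference and matched exactly on (contig, pos, ref, alt).
Sensitivity = TP/(TP+FN); specificity uses confident-region
non-variant positions (genome length minus truth count) as its
denominator, a choice stated in the report header since the field's
specificity denominators vary. Genotype-level matching additionally
requires the exact allele copy number.

## Problem sizes and determinism

The shipped experiments use a 250-kb genome for the 40x and 20x
end-to-end runs (~280 planted variants, ~50,000 read pairs at 40x), an
80-kb genome for the four-point depth titration, and a 20-kb genome
for the structural-extreme (263-nt deletion / 469-nt insertion)
recovery check — sizes chosen so the whole suite completes in minutes
on one CPU while keeping enough planted events for the percentages to
be meaningful. Every random draw flows from a single integer seed
(numpy Generator); identical seeds give byte-identical genomes, reads,
and calls, and calls are invariant to read input order.

## Known limitations

* The mapper handles forward/reverse pairs only (no RF/tandem
  layouts), has no alt-contig awareness, and emits SAM, not BAM/CRAM.
* Reference support at a site is defined as "no event at this exact
  position", so a haplotype whose deletion overlaps a neighboring
  site can be miscounted as reference support there; at the simulated
  variant density this is rare.
* The gap-open PCR model is a homopolymer-keyed stand-in; the
  polypyrimidine/splice-region rules use fixed distances rather than
  motif models; the cryptic-splice check is a dinucleotide heuristic.
* Structural variants beyond ~470 nt indels, repeat expansions, and
  pseudogene disambiguation are out of scope, as is gVCF output and
  multi-sample joint calling.
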