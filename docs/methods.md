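# Methods

This note documents the models and procedures implemented in mirpipe, the
defaults and why they were chosen, what the synthetic data emulates (and does
not), and the numerical choices a user relying on the outputs should know.

## Read preprocessing and mapping

Reads below `min_len` (default 17 nt) are discarded; identical sequences are
collapsed across libraries with per-library counts preserved. Mapping is
substitution-only seed-and-extend: the 5′ prefix of length
`min(seed_len, read length)` (default seed 18 nt) must match the genome
exactly, the tail tolerates up to `max_tail_mismatch = 2` substitutions, and
a read qualifying at more than `max_hits = 5` loci is dropped outright;
otherwise only the best alignment (fewest mismatches; ties by scaffold name,
then position, then '+' before '−') is reported. Indels are not modeled —
at 17–28 nt an indel-containing alignment is not credible under this
stringency class. For a 17-nt read the whole read is the seed. The k-mer
index defaults to word 17 so that 17-nt reads remain mappable; both strands
are searched by reverse-complement lookup. The mapper is tested for exact
equivalence against a brute-force scan of every genomic window on small
genomes.

The note on multiplicity: the drop rule is implemented literally as "more
than 5 hits dropped". Summaries that count unique sequences mapping "up to
4 locations" in other conventions can be reproduced by setting
`max_hits = 4`; the flag is configuration, and the package does not resolve
that ambiguity silently.

## Precursor excision, folding and scoring

A *stack* is a maximal set of overlapping same-strand alignments; stacks
with at least `min_stack = 5` summed reads are excised twice — once reading
the stack as the 5′ arm (70-nt downstream flank) and once as the 3′ arm
(70-nt upstream flank) — clipped at scaffold ends. The 70-nt flank is the
typical metazoan pre-miRNA scale.

Folding is a Nussinov-style maximum-weight pairing with weights GC = 3,
AU = 2, GU = 1, minimum hairpin loop 3 and no pseudoknots, filled in
O(n³) (numba-compiled) with a deterministic traceback. The negated optimum
is reported as `mfe_proxy` — a unit-free stability score, **not** kcal/mol;
it orders structures by pairing strength but has no thermodynamic meaning.
The folder is verified against exhaustive enumeration of all valid
structures for short sequences. Structural significance uses
Altschul–Erickson dinucleotide-preserving shuffles:
p = (1 + #{shuffles at least as stable}) / (n_shuffles + 1). The pipeline
default is 19 shuffles (granularity 0.05, the significance level actually
used); the function accepts any n ≥ 19 when finer p-values are wanted.

Reads inside a window are assigned by position: the highest-count read
defines the mature block and overlapping reads (isomiR wobble) count as
mature; a non-overlapping read is a **star** if it is ≥70 % identical to the
reverse complement of the mature over ≥15 nt at a duplex-like offset (±6 nt)
— a sequence test, deliberately independent of the global fold, which can
pair the mature with flanking sequence when the window extends beyond the
true precursor; remaining reads in the fold's loop region count as loop,
everything else as other. A trimmed hairpin core (mature through star, or
through the mature's pairing partners when no star read was sequenced) is
carried for homology, since the excised window is wider than a pre-miRNA.

The discovery score is an additive surrogate for read-stack discovery
scores, whose exact published models are proprietary to their tools; its
components and weights (configuration, `ScoreWeights`):

| component | default | rationale |
|---|---|---|
| signal-to-noise: `2.5 · log2((mature+star+1)/(loop+other+1))` | 2.5/bit | mature-arm dominance is the primary read-level evidence |
| star bonus (only when `0 < star ≤ mature`) | +2 | sequenced star reads are strong biogenesis evidence; a "star" outnumbering its mature is a misassignment |
| shuffle significance at α = 0.05 | +3 / −8 | a precursor must fold better than its dinucleotide shuffles; the asymmetric penalty keeps star-less single-block stacks from passing on read counts alone |
| stem term: `4 · (mature paired fraction − 0.75)` | | rewards pairing beyond what maximum-weight folding gives an arbitrary block anyway (the 0.75 baseline); breaks the tie between the two excision windows of one stack |
| malformed hairpin (mature not on one arm) | −10 | |

Candidates scoring ≤ −50 are removed from the candidate list entirely;
candidates must exceed 2 to be reported. Both thresholds are configuration
and sit at meaningful points of this scale: planted true hairpins score
≈ 15–30, background windows ≈ −10–+2. Because the stability test is a
permutation test at α = 0.05, a matching fraction of background read-stack
windows (≲5 %) will always clear the reporting threshold by chance; the
downstream homology-and-triage step is what removes them from the final
identified set, exactly as visual curation does in practice. Overlapping
candidates on one strand are collapsed to a single locus, preferring star
support, then score.

Exon-overlap classification is pure interval algebra against the annotation
(exon strand ignored — hairpin-vs-gene orientation is not informative for
the question being asked), with precedence within_exon > contains_exon >
overlaps_exon_boundary, then intronic (inside a gene span touching no exon),
else intergenic.

## Homology and orthologs

Mature queries are compared through shared exact 16-mers; a subject sharing
no 16-mer is invisible, which is precisely how the high word size restricts
matches to near-identity. Candidate offsets are compared ungapped over the
full overlap: *perfect* requires identity at equal length; *near-perfect*
(the iso-miRNA gate) tolerates one mismatch or up to a 2-nt length
difference. Precursors use seed-and-extend ungapped local alignment
(match +1, mismatch −2, X-drop 12 with running-max semantics and ties
extended for maximal coverage). The score gate (default 40) stands in for a
stringent E-value cutoff — true Karlin–Altschul statistics need a database
context this near-identity search does not have; it is calibrated so a
~45-nt perfect local match passes and anything under 16 nt cannot. Matches
leaving more than 8 query bases unaligned are discarded. Classification:
perfect mature match → known; near-perfect mature match or a surviving
hairpin match → iso; neither → novel candidate. Reciprocal best hits
between two hairpin sets (ties by score, then fewer mismatches, then
subject id) define orthologs; the pair set is symmetric in species order.

## Novel-miRNA decision tree

Evaluated in order on the presence matrix over sequenced libraries only
(a never-sequenced replicate shrinks denominators; it is not an absence):

1. present in every sequenced library → accept;
2. absent in exactly one replicate of one stage, present everywhere else →
   accept;
3. detected in ≥2 stages with ≥2 replicates each while absent in ≥1 whole
   stage → accept, unless total count < `min_total_count` (default 10) or
   no star reads (reject), or the hairpin is malformed (reject);
4. detected in a single replicate of a single stage → reject (candidates
   too sparse to fit any pattern above also land here);
5. any accept is vetoed if the mature read does not dominate its star.

"Present" means count > 0; `min_total_count = 10` sits below the smallest
plausibly-real stage-restricted total and above single-digit noise. The
35-candidate stratified fixture (1 ubiquitous, 1 single-missing-replicate,
7 stage-restricted of which 3 low-count/star-less and 1 malformed, 26
single-replicate) yields exactly 5 accepts.

## Expression

cpm divides by effective library size (column sum × normalization factor).
TMM factors follow the original weighted-trimmed-mean recipe: M-values
against a reference column (chosen by the 75th-percentile rule), 30 % / 5 %
trims on M and A, binomial delta-method precision weights, geometric-mean-1
rescaling; the implementation matches edgeR's `calcNormFactors` to 1e-6 in
the cross-check test. Differential abundance uses the conditional
negative-binomial exact test: per-library counts scaled to the
geometric-mean effective size and summed per stage; conditional on the
pooled total the split probabilities are enumerated with group-sum NB laws
(size n_group/φ), and the two-sided p-value sums probabilities no larger
than the observed split's (double tail; φ = 0 is the binomial/Poisson
limit). This matches edgeR's exact computation in its exact regime. The
common dispersion defaults to a method-of-moments estimate — the median
over informative genes of (var − mean)/mean² within stages — with a
configuration override; tagwise shrinkage is out of scope. BH adjustment is
applied within each contrast; all 10 unordered pairs of the five stages are
tested by default. Log2-ratio profiles use stage-mean cpm with a 0.5
pseudo-count over available replicates; clustering is complete-linkage on
Euclidean distances. Cross-species correlation is Spearman's rho per
library pair over ortholog pairs with data in both species; cells with
fewer than 5 informative pairs are flagged undefined.

## Target scanning

A site must contain an exact Watson–Crick complement of miRNA positions 2–7
(extension through position 8 / 1 upgrades to 7mer / 8mer; no wobble in the
seed). The full-length duplex is scored ungapped: +5 per WC pair, +2 per
G:U, −3 per mismatch, with miRNA-3′-half pairs at half weight. The −8/−8
affine gap penalties are honored by construction: at 22-nt duplex scale a
gap can never beat taking mismatches, so the optimal constrained alignment
is ungapped. Raw scores are rescaled so a perfect 22-mer duplex sits at
~190 (the conventional strong-site magnitude), letting the stringent gates
(score > 155, stability proxy < −7) act on familiar numbers; the rescaling
constant is configuration. Overlapping sites within 25 nt keep the best
score. The stability proxy is the negated pair-weight sum, unit-free like
`mfe_proxy`.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:
five stages × three replicates with one library unsequenced; 17–28-nt reads
dominated by mature sequences (77 %) with star (8 %), loop (5 %) and decoy
(10 %) fractions and 4.7 % of total reads below 17 nt; ±1-nt end wobble on
10 % + 10 % of mature reads; hairpins planted as perfect fold-backs with
one arm mismatch, singly (spaced ≥12 kb) and in tandem clusters (gaps
150–700 bp; one cluster carries family duplications with 1–2-nt paralog
divergence, since identical duplicated matures cannot be separated by any
best-alignment mapper); stage expression follows three canonical group
shapes (rising through development; larva-peaked; pupa-depleted/ovary-high)
with lognormal per-miRNA baselines and NB noise at dispersion 0.1 (matching
the exact-test model class); genes/exons/3′UTRs are planted to exercise
every overlap category plus one UTR carrying a perfect target site; decoys
are scattered single-copy genomic fragments on either strand — at
desk-scale depth/genome ratios (3 × 150 kb, 10 000 reads/library) a pooled
decoy design would tile the genome into artifactual mega-stacks no real
library produces — plus a 24-mer repeat inserted 6× to trip the
multiplicity filter. Reference databases emit known miRNAs with 0–2
substitutions cycling per entry, placed near the sequence ends so one
shared 16-mer survives (the regime the word-16 search is built for); novel
miRNAs are omitted; decoy entries match nothing. A second species'
expression is generated by a Gaussian copula at the Pearson correlation
2·sin(π·ρ/6) that induces a requested Spearman ρ.

Not emulated: platform-specific sequencing error and adapter chemistry,
full isomiR distributions, multi-loop precursors, true thermodynamic
folding, and real genomic base composition. Passing tests therefore show
the pipeline's logic and statistics are correct under the assumed data
model, not that the surrogate score reproduces any particular tool's
ranking on real libraries.

## Problem sizes and determinism

Everything is deterministic under a fixed seed (child generators are spawned
per component, so changing the seed changes data but never schema). The
default synthetic study uses a 3 × 150 kb genome, 25 planted miRNAs (20
known / 5 novel, clusters of 8 and 3) and 10 000 reads per library —
chosen so the full discovery chain, the 2 000-gene null calibration of the
exact test and the acceptance script each complete in tens of seconds while
leaving every rule with enough events to be exercised. Known limitations:
the surrogate score's absolute scale is not comparable to published
discovery scores even though its thresholds play the same roles; the exact
test uses a single common dispersion; cluster arrangement comparison is on
family-label sequences, not alignment; and E-value emulation in homology is
a calibrated score gate, not database statistics.
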