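# Methods

## Coordinate model and alignment identity

All coordinates are 0-based half-open internally (the PAF convention);
GFF3 and VCF are converted at the boundary. Alignment identity is defined as
PAF column 10 over column 11 (residue matches over gap-inclusive block
length). This is a BLAST-like, gap-inclusive identity; the optional `de:f`
divergence tag is ignored because columns 10/11 are mandatory in every PAF
dialect, making the definition aligner-independent. Whether a
"percent identity" filter should be gap-compressed is genuinely open; the
gap-inclusive reading is the conservative one (it can only be lower).
Alignment retention filters are strict inequalities (length > threshold,
identity > threshold, mapq > threshold), matching the usual "alignments
> 10 kb, identity > 0.85" phrasing of such filters; a threshold of zero
disables the corresponding check.

## Contig breakpoints and telomeres

Contig breakpoints are the start and end positions of N-run gaps of at least
`min_n_run` bases (default 10 bp; scaffolding pipelines typically pad joins
with 10,000 Ns, but a low default also catches short within-contig N
patches). Scaffold termini are not breakpoints — the mis-orientation risk
concerns joins between contigs, not chromosome ends. Telomeres are located
by counting exact non-overlapping copies of the plant telomeric motif
(TTTAGGG toward the 3' end on the forward strand, its reverse complement
CCCTAAA at the 5' end) within a terminal window (default 10 kb), calling a
hit at ≥ 25 copies. Exact-match counting was chosen over fuzzy matching for
testability; degenerate telomeric repeats will undercount, so the copy
threshold is deliberately low relative to real telomere arrays (hundreds to
thousands of copies).

## Inversion calling and breakpoint-aware filtering

The caller operates per target sequence on filtered alignments: blocks
sorted by target position define a majority-strand syntenic chain (majority
by aligned target length, so assemblies with globally flipped chromosomes
are handled). Maximal runs of opposite-strand blocks whose query coordinates
run counter to the chain, with adjacent target gaps ≤ `max_chain_gap`
(default 100 kb), merge into one call; runs that jump query chromosomes are
split with a warning, and calls spanning < `min_block` (default 10 kb) on
the query are dropped. A SyRI-format import (`INV` rows, 1-based inclusive
converted on read) is provided for users who prefer the external caller.

An inversion is "near" a contig break on one assembly when **either**
endpoint of its region on that assembly is within *d* (default 2 kb) of
**any** breakpoint on that sequence; the summary tally counts calls
flagged on both assemblies in both "near" columns (so percentages need not
sum to 100) while the filtered set requires both flags false. Gene content
of filtered inversions uses ≥ 1 bp overlap, each gene counted once; density
is genes per kb of filtered query span, undefined (NaN) with zero filtered
calls.

Boundary enrichment is defined as observed/expected with
observed = fraction of the 2·N inversion boundaries within *d* of a
breakpoint and expected = fraction of assembly bases within *d* of any
breakpoint (intervals [b−d, b+d) unioned and clipped to sequence ends).
The permutation null re-places the observed number of boundaries uniformly
at random per sequence; p = (1 + #{perm ≥ obs}) / (1 + n_perm), the
standard add-one Monte-Carlo estimator, which is super-uniform under the
null. The seed is a required argument — enrichment results are only
comparable across runs when the permutation stream is pinned.

## Windowed competitive ancestry

Windows are anchored at position 0 of each scaffold (default width 100 kb);
a final partial window is kept when it covers at least half the width. Each
alignment contributes its window overlap and overlap×identity to its
ancestor's accumulator; a window's ancestor identity is the length-weighted
mean, set to NA below a coverage floor of 10% of the window. The winner
needs a non-NA identity and, when both ancestors are callable, a margin of
≥ 0.002 over the other — "preferentially aligned" has to be operationalized
somehow, and at progenitor divergences of 5–15% the true-ancestor identity
gap (roughly the ancestor divergence itself) dwarfs this margin, while ties
from near-identical tetrasomic copies fall below it. Homeolog windows are
paired by rank along the chromosome (k-th window with k-th window), which is
deterministic and adequate when homeologs are collinear at window scale; a
synteny-based pairing can be supplied for rearranged chromosomes.

Pair labels follow from the two winners (expected / tetrasomic_A /
tetrasomic_B / exchanged, with any no-call giving ambiguous). Runs of ≥ 3
identical non-ambiguous labels become regions; single ambiguous windows
inside a run are bridged first, shorter runs dissolve into ambiguous. The
competitive and subgenome-specific modes share the labeling rule — they
differ only in which alignments are supplied — and this module does not
re-resolve multi-mappers beyond what the supplied best-placement alignments
already encode.

## Introgression origin and segmentation

Per-scaffold origin against two references uses the aligned fraction
(union of query intervals of filtered alignments, so overlaps are not
double-counted) with a decision margin of 0.1. Coverage rather than
identity decides, because a diverged wild-relative haplotype still aligns at
95%+ identity within conserved regions but covers an order of magnitude
less of the wrong reference — identity is high for both candidates and
carries almost no signal.

Within-scaffold segmentation consumes per-window best-placement read counts
(a helper bins read midpoints from a mapping PAF). Each window takes its
majority source (ties are no-calls); runs shorter than `min_run` merge into
the flanking run with more total votes, iterating from the weakest run until
stable. Breakpoints are the window boundaries between adjacent segments.
A run-length rule was chosen over an HMM deliberately: at window scale with
near-unanimous votes the HMM adds parameters without adding power. On the
default fixture the pipeline uses `min_run` = 3 (the 400-kb planted tract is
4 windows wide); the library default of 5 suits longer tracts.

## Trio classification

Each VCF record is decomposed per alternate allele; genotypes are recoded
as 0 (reference), 1 (this alternate), 2 (any other allele). A site is a
parental fixed difference only in the strictly biallelic configuration
(parents homozygous 0 and 1, offspring carrying no third allele); offspring
are then hom-ref / het / hom-alt, with missing offspring genotypes excluded
from percentage denominators. Offspring alternates absent from both (called)
parents are non-parental; offspring alternates shared with at least one
parent are shared-alternate. Optional GQ/DP floors demote failing sites to
uninformative, and an exclusion list drops whole chromosomes (useful when an
alternate haplotype scaffold inflates apparent variation on its chromosome).

## The synthetic fixture

The generator's default configuration is the published fixture (seed 42):
two chromosome pairs of 2 Mb; progenitor divergence 0.10, per-genotype
divergence 0.02, donor divergence 0.08; one 400-kb exchange tract, one
400-kb tetrasomic tract, two inversions (100 kb and 150 kb), one 400-kb
donor introgression plus a full donor-derived alternate haplotype scaffold;
two 10-kb N-gaps per scaffold, one of whose edges lies 1 kb from an
inversion boundary so that the breakpoint-proximity filter has a true
positive to catch; a 4,000-site trio VCF with a 10% outcross fraction.
Divergence values sit in the range typical of congeneric plant progenitors
and of the distance between a cultivated species and its wild relatives.

All mutations are substitutions, so coordinate maps between genomes are
length-preserving and PAF records can be emitted exactly from the
provenance bookkeeping: block boundaries fall at every planted feature, gap
and conserved-island edge, and each block's identity is one minus its
realized mismatch fraction (for a chain of substitution rounds at rates
r_i, the expected mismatch fraction has the closed form
(3/4)·(1 − Π(1 − 4r_i/3)), which the tests use as the oracle). Comparisons
across the species boundary (donor-derived vs progenitor-derived sequence)
are emitted only over a regular grid of conserved islands (15 kb per
100 kb), where the donor mutates at 0.3× its rate — mimicking the
fragmented, low-coverage, high-identity alignment pattern of a diverged
donor; cross-species blocks over inverted spans are skipped, as real
aligners usually fragment there. Reads are exact 10-kb tiles assigned to
the reference with fewer mismatches; reads over gaps or inverted spans are
unplaced.

What the generator does **not** emulate: indels and structural variation
beyond the planted classes, repeat-driven mis-mapping, aligner chaining
artifacts, sequencing error, segregation/recombination in the trio, or
coverage variation. Passing tests therefore demonstrate correctness of the
computations given faithful alignments, not robustness to aligner noise —
on real data the alignment filters carry that burden.

Randomness is partitioned from the master seed into independent streams
(genomes, trio, genes) via seed-sequence spawning, so outputs are
byte-identical across runs of the same seed.

## Numerical and degenerate-input conventions

Percentages are reported to 1 decimal, densities to 4; report floats render
at 4 decimals. Report tables emit only the internal 0-based half-open
coordinates — duplicating every position in a second 1-based inclusive
column set invites exactly the off-by-one confusion a single convention
avoids. Zero filtered inversions give NaN density; zero inversions
give enrichment 0 and p = 1; an all-tie vote track gives an empty
segmentation; an empty site list gives NaN percentages. Majority-strand
ties in the caller default to "+"; vote ties in segmentation are no-calls
absorbed by the flanking merge (left flank on equal votes).

## Known limitations

Rank-based homeolog pairing assumes window-scale collinearity between
homeologs. The inversion caller is a single-pass chain heuristic — nested
or translocated inversions are out of scope, as is base-level breakpoint
refinement. Telomere detection is exact-match only. Enrichment compares
boundaries to breakpoints marginally; it does not model the joint spatial
process of repeats driving both. The problem sizes of the bundled fixture
(desk-scale megabase chromosomes) exercise every code path; absolute counts
from multi-gigabase genomes will of course differ.
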