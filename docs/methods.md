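# Methods

`hybridscan` profiles genomic instability in interspecific hybrid genomes
from short reads: which species contributed how much of the nuclear and
mitochondrial genome, which chromosomes were gained or lost, how similar
hybrid genomes are to one another, and where heterozygosity has been lost.
Every stage is paired with a synthetic cohort generator so the whole
pipeline can be verified by parameter recovery without any external data.

## Synthetic cohorts

The generator produces two collinear parent genomes per cross under a
substitution-only divergence model: each site of parent 2 is substituted
(always to a different base) with probability `divergence`. Interspecific
*Saccharomyces* parents span roughly 10–22% genome-wide nucleotide
divergence; the model is capped at 25%, where independent-site
substitution starts to saturate. Keeping the parents collinear (no indels)
means both subgenomes share one coordinate system, which is what the
marker-based LOH logic assumes. Coordinates are 0-based half-open
internally, BED dialect on export.

A hybrid is a pair of parental subgenomes with per-chromosome copy
numbers (baseline 1+1; whole-chromosome gains/losses only — the calling
unit downstream is the chromosome), an expected read fraction per parent
(`contribution`), a homoplasmic mitochondrial donor (species, clade; one
species may carry several divergent mitochondrial clades), optional LOH
tracts (within a tract the lost parent's template carries the retained
parent's sequence), and optional high-copy repeats that inflate local
depth.

Reads are single-end, uniform start positions, Poisson count per
template, both strands, uniform substitution errors — the simplest model
that exercises depth-based calling. A chromosome copy from parent *sp* is
sequenced to expected depth `coverage * 2 * contribution[sp]`, so a
balanced euploid hybrid has total depth `2 * coverage` per homeologous
pair and a trisomy sits at 1.5x the genome-wide total. Mitochondrial
reads come only from the donor haplotype at `mito_ratio` (default 10)
times the nuclear per-copy depth, mimicking organelle over-representation.
Read names encode sample, true origin species, chromosome, start and
strand, which is what recovery tests score against.

What the generator does **not** model: indels and rearrangements, paired
ends, quality scores, GC/mappability bias, segmental aneuploidy,
heteroplasmic or recombinant mitochondria, more than two parents.
Passing recovery tests therefore demonstrate the correctness of the
statistics under idealised mapping conditions, not robustness to
alignment artefacts on real libraries.

## Ancestry: diagnostic k-mers as a competitive-mapping surrogate

Competitive mapping against a combined multi-species reference is
replaced by an alignment-free equivalent: a canonical k-mer (k = 17, odd
so no k-mer is its own reverse complement; canonical = lexicographic
minimum of the two strands) that occurs in exactly one parent genome is
diagnostic for that species. A read is assigned to the species with the
most diagnostic hits if the top count is at least `min_hits` (default 2)
and leads the runner-up by at least `min_margin` (default 2); ties are
AMBIGUOUS and zero-hit reads UNASSIGNED. Two independent diagnostic
k-mers suppress error-induced false hits, playing the role of a
mapping-quality floor. The read's placement is the reference position of
its first diagnostic k-mer minus the k-mer's offset (strand-aware) —
exact under collinearity, and amply precise for 10 kb windowing.

Per-sample contributions are fractions of **all** reads; ambiguous and
unassigned fractions are reported separately and the three groups close
to 1. A sample enters the depth analysis only if at least 85% of reads
were confidently assigned and exactly two species each hold at least 5%
of assigned reads. The 5% parent floor is this package's own threshold
separating parental signal from small introgressions; it is configurable.

Mitochondrial assignment runs against a disjoint index of mitochondrial
haplotypes, one source per (species, clade); a species is scored by its
best clade (homoplasmic inheritance makes reads pile on one haplotype)
and the majority species is the argmax, undefined on exact ties. A read
claimed by the mitochondrial index is routed there in preference to the
nuclear index (organelle copy number). Whether the mitochondrial majority
matches the nuclear majority (concordance) is tested across a cohort with
Welch's unequal-variance t-test on the majority-nuclear percentage,
closed-form with Welch–Satterthwaite degrees of freedom; a group with
fewer than two members makes the comparison NOT_TESTABLE rather than an
error.

## Karyotype: read-depth aneuploidy

Depth is summarised in 10 kb tiling windows per subgenome (terminal short
windows are kept and width-weighted rather than dropped — small
chromosomes are the very objects of interest). A window whose depth
strictly exceeds twice its chromosome's width-weighted mean window depth
(one log2 unit) is masked as a suspected unresolved repeat and excluded
from all chromosome statistics. The chromosome mean in that rule is
computed in one pass including the candidate window; an iterative
variant (re-excluding until stable) is available behind a flag, the
one-pass form being the deterministic default.

Per-chromosome total depth is the sum of the two subgenome means,
`D_c = D_c,sp1 + D_c,sp2`; the genome-wide mean `D_G` is the
chromosome-length-weighted mean of the totals, i.e. the width-weighted
mean of total depth over the unmasked genome, putting `D_G` on the same
(total) scale as `D_c`. A chromosome is GAIN if `D_c > 1.3 * D_G` and
LOSS if `D_c < 0.7 * D_G`, strict inequalities at both thresholds (and at
the 2x mask rule): depth exactly at a boundary is not evidence of change.
Calls are made on total depth; per-species means are reported but not
independently thresholded.

Genome-level statistics: the chromosomal variance is the sample (n−1)
variance of the `D_c` (genomes are draws from a stochastic process;
switchable); the per-chromosome depth change is `Δ_c = |D_c − D_G|`; the
size relation is ordinary least squares of `Δ_c` on chromosome length,
per genome and pooled across genomes, with Pearson r and two-sided p for
the pooled fit. Cross-level heatmaps normalise each chromosome column
two-sidedly: minimum cross mean to 0, overall mean to 0.5, maximum to 1.
All calls and correlations are invariant to rescaling depth; variance
scales quadratically.

## Shared k-mer networks

Each sample is reduced to its set of canonical 17-mers observed at least
`min_count` times — 5 by default, with 2 as the read-depth sensitivity
variant; the threshold is inclusive, and distinct sets (not
count-weighted multisets) are compared. Counting is exact and in-memory
(2-bit packed 64-bit codes; roughly 16 bytes per distinct k-mer during
counting, comfortable at desk scale). Pairwise shared counts `S_ij` feed
a distance `D_ij = −(1/k) · ln(S_ij / min(|A_i|, |A_j|))`; this is the
simplified alignment-free form without coverage/tip corrections, and the
raw `S_ij` are always exported so any other estimator can be recomputed
downstream. Pairs sharing no k-mer have no finite distance and are capped
at 1.1x the largest finite entry (flagged, and warned about in exports)
to keep matrices usable by network software. Matrices export as square
PHYLIP or a NEXUS Distances block (labels whitespace-sanitised); network
layout itself is out of scope.

A subtlety worth recording: the direction of the shared-k-mer vs
parental-divergence relation depends on hybrid genome structure. Between
fully heterozygous balanced hybrids, sharing *grows* with divergence
(both samples carry the whole parental union, which contains more
distinct k-mers the more the parents differ). Between segregant-like
mosaics — genomes homozygous chromosome-by-chromosome for one parent or
the other, the structure of old stabilised hybrids — sharing *falls* with
divergence, because two mosaics only share conserved k-mers where their
retained parents differ. The monotonicity validation therefore uses
mosaic hybrids.

## Loss of heterozygosity

Under collinearity every differing parental site is a single-nucleotide
marker. Placed reads vote strand-aware for the parent 1 or parent 2
allele at each marker they cover — reads are used regardless of assigned
species, since inside an LOH tract the lost subgenome's reads carry (and
are assigned to) the retained parent anyway, and position on the shared
coordinate system is what matters. A marker is HOM_P1 when the parent-1
fraction of informative depth is at least `purity` (default 0.9), HOM_P2
symmetrically, HET otherwise, NO_CALL below `min_depth` (default 3).
LOH segments are maximal runs of at least `min_run` (default 10)
same-parent homozygous markers; NO_CALL markers are transparent (missing
data is not evidence of heterozygosity) while HET or opposite-parent
calls break runs. At 10% divergence (one marker per ~10 bp) these
defaults put the false-segment rate under binomial sequencing error far
below one per genome, which the 20-seed false-positive study confirms
empirically; both knobs are configurable. Segment coordinates span first
to last marker, so breakpoints are recovered at marker resolution.
An optional BED exclusion list supports subtelomere masking (off by
default; the simulator does not model subtelomeres). Copy-number-aware
LOH (hemizygosity) is not inferred.

Cohort maps report, per 10 kb bin and per direction, the fraction of
samples whose matching segments cover at least half the bin — restricted
to hybrids that inherited at least 20% of their nuclear genome from each
parent. The per-sample LOH extent is reported as percent of genome in
segments; a cohort average of these is the headline extent statistic.

## Validation studies and problem sizes

`hybridscan.validation` fixes the recovery experiments that both the test
suite and `scripts/acceptance.py` run: divergence 0.10, 20x coverage,
100 bp reads, 0.1% error, and a scaled-down eight-chromosome karyotype
(48–6 kb, 179 kb total) whose ~6–8x relative size spread mirrors real
yeast chromosomes (230 kb – 1.5 Mb); assignment-heavy studies use a
compact six-chromosome 95 kb variant. These sizes keep every study's
statistics well-powered (e.g. chromosome-mean depth noise under 1% at
20x, against a 30% call threshold) at desk-scale runtimes. The
size-direction study plants aneuploidies with probability proportional to
1/length at ~1.5 expected events per genome — an unstable cohort in which
most genomes carry at least one deviation — and recovers a negative
pooled slope with >90% of per-genome slopes negative.

## Configuration

`report.run_pipeline` drives all stages from one mapping with keys
`seed`, `out_dir`, `stages` (subset of ancestry/karyotype/kmer/loh),
`crosses` (list of `CrossSpec` fields), and `params`. All analysis
thresholds are `params` keys with the defaults above
(`min_assigned=0.85`, `aneuploidy_threshold=0.30`, `mask_fold=2.0`,
`k=17`, `min_count=5`, `min_run=10`, `purity=0.9`, `min_depth=3`,
`min_parent_frac=0.20`, `window_size=10000`, `bin_size=10000`,
`min_hits=2`, `min_margin=2`, `parent_floor=0.05`). Unknown keys raise
naming the key. Runs are deterministic given the configuration: seeds
derive from one root via `numpy` seed sequences, outputs are written with
fixed formatting, and every artifact is stamped with a hash of the
analysis-relevant configuration; each inclusion/exclusion decision is
logged with its rule.
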