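# Methods

## Scope and model

A segmental duplication (SD) is operationally defined as a pairwise local
alignment of two distinct genomic loci with aligned length ≥ 1,000 bp and
identity ≥ 0.90. The package detects SDs by two complementary routes and
combines them; all statistics operate on 0-based half-open intervals (BED
convention) throughout, on disk and in memory.

## Self-alignment (WGAC)

Known common repeats are removed before alignment by *excision*: repeat
bases are deleted and a coordinate map records the retained positions, so
condensed coordinates lift back to assembly coordinates exactly. This
prevents abundant interspersed repeats from seeding spurious alignments,
while duplications interrupted by a repeat still chain across the gap.

The aligner is seed–chain–extend, gap-free:

* exact k-mer seeds, k = 14 (base-5 integer codes; k-mers occurring more
  than 100 times are skipped as unmasked satellite);
* seeds sharing a diagonal are chained when spaced ≤ 250 bp; chains
  spanning < 100 bp are discarded (a genuine 1 kb / 90% alignment contains
  an exact 14-mer roughly every 4–5 bp, so its chain spans nearly its full
  length);
* chains are extended outward by X-drop gap-free extension
  (match +1, mismatch −2, X-drop 20, single-sided cap 60 kb);
* the extended span is trimmed to the **longest contiguous window whose
  identity stays ≥ the floor** (integer prefix scores, monotone-stack
  longest-window search; leftmost window wins ties). Alignments below
  1 kb or 90% after trimming are dropped.

Gap-free alignment is adequate because the divergence model of both the
simulator and the identity definition is substitution-only; indel-bearing
duplications would fragment into collinear gap-free pieces. The reverse
strand is handled by aligning the genome against its reverse complement;
chromosomes are separated by 50-base sentinel runs that no extension or
read placement can bridge. Reported pairs are canonically ordered
(locus_a ≤ locus_b), deduplicated, and alignments whose both loci are
>50% contained in a longer alignment's loci are dropped as redundant.
Identity is reported to 4 decimals.

**High-copy cleaning.** Duplicated loci are clustered into duplicon
families: the two loci of an alignment are linked, and loci overlapping on
the genome are linked (single linkage). A family is removed whole when its
merged loci count ≥ 50 copies or fall on ≥ 3 distinct chromosomes — the
signature of an interspersed repeat that escaped the input annotation
rather than a segmental duplication. The filter is idempotent.

## Read-depth detection (WSSD)

Reads (36 bp by default) are placed at **every** locus with ≤ 2
substitutions (≈ 94% read identity, matching the stringency of the
high-identity WGAC range). Candidate loci come from the pigeonhole
principle — one of three 12-mer read segments must match exactly — looked
up in a sorted genome k-mer index; all arithmetic is vectorised. A read's
depth contribution is split equally among its equal-best loci; suboptimal
placements within the budget are not retained, since they would dilute the
copy-number signal deterministically. This equal split is what creates
the WSSD signal: loci present in the sequenced individual but collapsed in
(or absent from) the assembly pile their reads onto the assembly copy.

Depth is profiled in 5 kb windows sliding by 1 kb as mapped read bases per
non-repeat base; windows with < 50% non-repeat bases are uncallable. The
background is the 5%-per-tail trimmed mean/SD of callable windows outside
any self-alignment locus; trimming makes the calibration robust to a few
percent of residual duplicated sequence. Windows with depth
> mean + 3 SD are flagged and merged; each merged candidate is then
**refined to base-level boundaries**: a 1 kb rolling mean of per-base
depth is thresholded at the midpoint between background and the
candidate's robust peak (95th percentile), and the longest contiguous run
above that level is the reported interval. The half-height level sits many
background SDs above the noise, so flank fluctuations cannot drag the
boundaries outward the way the raw z-threshold would; without refinement,
window smearing inflates a 6 kb excess region to ~12 kb and the ≥ 10 kb
reporting floor would lose its meaning. Intervals ≥ 10 kb are reported
with absolute copy number 2 × mean depth / background (diploid baseline,
one decimal). Heterogeneous candidates containing segments of very
different copy number are trimmed relative to the dominant peak — a known
limitation.

## Combination rule

Cleaned alignments are split at 94% identity (≥ 0.94 goes to the high
side). Low-identity alignments enter the final map directly. A
high-identity alignment survives only when WSSD intervals cover ≥ 50% of
at least one of its loci; the rest are logged as artifactual. The final
map is the base-level union of surviving loci, annotated with support
class, maximum contributing identity, and the copy number of the
largest-overlap WSSD interval. WSSD intervals with no overlap with the map
are reported as a separate depth-only track and are **not** counted in the
map or the SD content (the final database is alignment-derived, with read
depth used as a filter). The verification proportion restricts to loci
longer than 10 kb at ≥ 94% identity and reports verified/total merged
length; it is NaN (with a warning) when no locus qualifies.

## Permutation enrichment

Query regions (merged first; the SD map is already disjoint) are
re-placed uniformly at random: chromosome chosen proportional to length,
start uniform over the feasible range, mutual overlap rejected, lengths
preserved. The overlap statistic is either the number of landmark
intervals hit (count), the number of query intervals hit (used for gene
counts), or the intersection length. With n replicates the upper-tail
empirical p is (1 + #{null ≥ observed}) / (1 + n) — never zero, so 10,000
replicates with no exceedance reports p < 10⁻⁴; the lower tail is reported
alongside. Fold is observed / null mean. Landmarks: subtelomeric = first
and last 2 Mb of each chromosome, pericentromeric = 2 Mb on both sides of
the centromere (300 kb for designated short chromosomes); chromosomes
without a centromere contribute subtelomeric regions only. Gene-family
enrichment shuffles the family genes against the fixed SD map and
optionally reports the non-family fold as a contrast; the null is always
random placement. Multiple-testing correction across landmark sets is
left to the user.

## Gene content

Genes overlap the merged SD map by ≥ 1 bp (configurable); each gene's
copy number is that of the WSSD interval with the largest overlap, or Null
when none overlaps. Copy-number bins are right-closed at
1.5, 2.5, 10.5, 20.5, …, 100.5 with a Null row; the average is over
non-null genes to one decimal. Cross-species common genes are computed
through an input ortholog TSV into a shared reference namespace
(many-to-one allowed, unmapped ids counted, never fatal), with full
Venn-style combination counts.

## Synthetic data

The simulator generates i.i.d. nucleotide sequence at a configurable GC
fraction (default 0.42) and plants: duplication events (source + copies,
per-copy substitution divergence ≤ 0.12, tandem / intrachromosomal /
interchromosomal; every applied substitution is logged and realized
identity recorded), high-copy repeat families (100–1000 bp, ≥ 50 copies,
dispersed over ≥ 3 chromosomes, returned as the repeat mask), and
uniform-coverage 36 bp reads with uniform substitution errors (default
0.5%). Copies flagged donor-only are **inserted** into the donor genome
(appended to their chromosome): the sequenced individual carries extra
sequence, so reads from those copies pile excess depth onto the reference
source locus without deleting any unique region — replacement semantics
would zero coverage at the placeholder locus and corrupt background
calibration. True absolute copy number of a planted family with D donor
loci collapsing onto R reference loci is 2 D / R.

The canonical fixtures: *small* (3 × 350 kb, 8 events) and *standard*
(5 × 1 Mb, 30 events with lengths uniform over 1–50 kb and target
identities uniform over 0.90–1.00, each with one donor-only extra copy;
one 60-copy 1.5 kb family and one 3-chromosome family planted as designed
artifacts; a 200-copy 300 bp masked repeat family; 20× reads). Problem
sizes were chosen so a full standard run completes in roughly a minute on
one CPU while every rule of the method is still exercised at its stated
thresholds. What the simulator does **not** emulate: indels and
rearrangements, GC- or position-dependent coverage bias, quality-score
profiles, diploid heterozygosity, and realistic repeat taxonomies —
passing tests demonstrate the algorithmic contracts, not performance on
real sequencing artifacts.

## Reproducibility and numerical choices

All randomness flows from a single seed through per-stage seeds
`sha256(seed:stage) mod 2^31`. Ties in chaining are broken by (chromosome,
start); identity histogram bins 90–99 are half-open with exact 1.0 in
bin 100. Empty inputs return empty outputs; undefined statistics (empty
gene family, zero qualifying loci) signal explicitly rather than crash.
The run manifest records the config, per-stage record counts and output
checksums in a `determinism` block (the output directory path and wall
times are kept outside it), so two runs with one config can be compared
bit for bit.

## Known limitations

* Gap-free alignment fragments indel-bearing duplications.
* Equal-best depth splitting assumes unbiased mapping; paralog-specific
  variants in real data skew the split.
* Copy numbers of called intervals are means over the refined span;
  nested duplications of different multiplicity are averaged.
* The placement null treats the genome as homogeneous (no gap/assembly
  masking, no GC matching); segmentation-aware nulls are out of scope.
* Events shorter than ~9 kb at ≥ 94% identity cannot be validated by read
  depth (the ≥ 10 kb interval floor) and are excluded from the final map
  by construction.
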