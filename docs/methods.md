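# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of the methods documentation of simulation-heavy
genomics libraries.

## Coordinates, strands and tracks

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the I/O boundary. NET-seq and PAR-CLIP signal is stranded: a
`SignalTrack` holds one vector per chromosome per strand, and a transcript's
signal is always read from its own strand only. ChIP coverage is unstranded
(single vector, strand code `"."`).

NET-seq position semantics: one count at the 5′-most genomic coordinate of the
aligned read on the transcript's strand, representing the RNAPII active-site
position. Whether counts should sit on the read 5′ end or the RNA 3′ end after
orientation flipping is a convention choice; this package fixes the single
convention above and the synthetic generator and all consumers share it, so
analyses are internally consistent either way.

BedGraph reading treats overlapping records as an error rather than summing
them: overlapping intervals in a per-nt export almost always indicate a
malformed file, and failing early is cheaper than a silently doubled track.

## Pause peaks, clusters and dwell times

Robust Z-scores use the median/MAD form with the 1.4826 consistency constant
(MAD estimates σ for normal data). If the MAD is zero the sample standard
deviation is the fallback; if that is also zero the region is degenerate and no
peaks are called. Z is computed over log2 counts of the *covered* positions
only: zero positions carry no evidence of an engaged polymerase, there is no
defensible pseudocount, and a zero-read position could never satisfy the
10-read support threshold anyway.

The clustering window grid is anchored at the region start and advances by
`step`; two peaks co-cluster iff some window contains both, and clusters are
the transitive closure (for sorted peaks this reduces to chaining adjacent
pairs). Cluster extent is clipped to the member peaks, not the window bounds,
so density reflects the occupied span; "reads in the cluster" counts every
read start inside the span, including non-peak positions. `width < step` is
rejected because the tiling would leave gaps.

Fragment-level genotype comparisons assign each cluster to the single fragment
containing its midpoint. The repeat-region fragments deliberately overlap, and
midpoint assignment prevents one cluster from being counted twice within a
sample. Per sample, fragment scores are normalized by the sum of all cluster
densities, so library depth cancels; ratios are taken per replicate pair and
reported with the replicate range as error bounds. Fragments with no clusters
in the numerator genotype are flagged `n.p.`; a positive numerator over a zero
denominator is flagged infinite rather than silently dropped.

Dwell time is peak reads divided by the mean of the surrounding 100 nt (50
each side, peak excluded, truncated at chromosome ends); an empty or all-zero
flank yields +inf, which serialized outputs carry as a flag and distribution
comparisons exclude.

Dependence classification requires a peak called at the *exact same position*
in both baseline replicates (NET-seq is single-nucleotide resolution, so no
positional tolerance is applied) and a ≥ 2-fold RPM decrease in the mutant in
each replicate pairing, comparing the mutant's signal at the position rather
than requiring a mutant peak call (the mutant may fall below the calling
threshold precisely because the pause is lost). A mutant signal of zero counts
as an infinite fold decrease.

## Traveling ratios

Eligibility: a transcript must overlap no other annotated transcript on
*either* strand (the stricter reading of "non-overlapping", preventing
antisense signal bleed), be ≥ 1 kb (so the two 500-nt windows cannot overlap)
and carry ≥ 50 read starts in the analysed sample; when genotypes are
compared, the table is restricted to transcripts eligible in both. The 3′
window is the 500 nt strictly upstream of the cleavage/polyadenylation
coordinate, end-exclusive. Windows follow transcription direction, so on the
minus strand the 5′ window abuts the higher genomic coordinate.

Before K-means, TRs are floored at 0.01 and log2-transformed: ratios are
scale-typed and heavy-tailed, and a zero window (legitimate) must not map to
−inf. Clustering runs on one replicate of each genotype (feature vector:
log2 tr5/tr3 in each genotype); KS comparisons run per replicate pairing.
Cluster labels are relabeled by descending cluster size (ties by ascending
first centroid coordinate) so indices are stable across runs; any I/II/III
naming is presentation order only.

## PAR-CLIP coverage

The probabilistic cluster caller that produces candidate binding sites is out
of scope; candidates come from a BED-like file or the generator. The package
implements the published support filters (reads < 20 nt removed first, then
≥ 10 reads and ≥ 2 T→C conversions) and the coverage-fraction statistic
(union length of strand-matched cluster∩interval over interval length).
Flattening of identical recurrent sequence clusters is an optional dedup flag
keyed on (interval, strand).

## ChIP smoothing, background and PIER discovery

Smoothing is a centered 1-kb moving average (mean, not sum — the enrichment
ratios that follow are scale-free either way, but a mean keeps track units
interpretable), truncated and renormalized at chromosome ends so telomere-
proximal signal is not zero-padded away; for even windows the extra position
goes downstream.

"Genome background" is the median of the smoothed track outside a mask
(curated nucleation sites plus parental enriched regions): the genome is
mostly silent, so the masked median is robust to any number of true domains.
Enriched regions are maximal runs ≥ 3× background, with sub-kb runs dropped
and gaps < 1 kb merged — reported domains are at the multi-kb scale, and
sub-kb calls at a 1-kb smoothing bandwidth are noise. Both thresholds are
configurable.

Criterion (2) operates on the per-nt enrichment ratio e = (IP + ε)/(WCE + ε)
with ε = 0.5 RPM; the pseudo-signal avoids division by zero in unmapped
regions and biases the ratio toward 1 exactly where coverage is too thin to
support a call. The criterion-2 "background" is the masked median of the
ratio track itself (not of the raw IP), so both sides of the comparison live
on the same scale; the parental comparison uses the parental IP over the same
WCE, as only one whole-cell extract is modeled. Parental enriched regions are
computed with the same parameters as the isolate's, for symmetry. Exclusion
distance is boundary-to-boundary (0 if overlapping) — the strictest reading
of "within 10 kb". Each candidate carries exactly one exclusion reason, with
proximity reasons taking precedence over `below_threshold` (a domain shared
with the parental strain fails both, but "present in parental" is the
informative label).

Region-enrichment heatmap values are (region RPKM / flank RPKM) in the
isolate divided by the same ratio in the WCE, with the flank the 5 kb on each
side of the region (region excluded, truncated at chromosome ends); a zero or
empty flank yields a flagged missing value. The construction is invariant to
global rescaling of any single track.

## Synthetic data generator

The generator emulates, per assay, the statistical structure the analyses
assume — not read-level sequencing:

- **NET-seq**: Poisson(0.2)/nt background inside transcripts on their own
  strand, Poisson(0.002)/nt mapping noise genome-wide, and planted pause
  sites adding Poisson(wt_reads) in the baseline and Poisson(wt_reads/fold)
  in the mutant. Factor-dependent pauses (default half of the 40 planted, at
  exact class counts) are drawn at 5× the height of independent ones and a
  4-fold mutant decrease — long-lived pauses are the dependent class's
  defining property, and 5× is the separation the dwell-time comparison is
  specified against. Genes in a boosted traveling-ratio class carry extra
  5′-window signal (boosts 6×/2×/0× of background at class proportions
  0.224/0.546/0.230, following the reported cluster sizes 373/911/383) that
  relocates uniformly over the body in the mutant, conserving expected
  transcript totals so TR directionality is attributable to redistribution,
  not expression change.
- **ChIP**: flat Poisson rates scaled to ~1e6 reads per track; IP rates are
  multiplied by each domain's enrichment fold (isolate: all domains;
  parental: only `in_parental` ones). Replicates are fresh Poisson draws over
  shared truth, matching a duplicate experimental design.
- **PAR-CLIP**: clusters are tiled per transcript until the class coverage
  target is hit to within rounding (repeat 0.60, coding 0.05, ncRNA 0.90);
  true clusters draw counts above the filter thresholds, decoys below. The
  repeat/coding target ratio is 12, matching the reported fold; the reported
  ~100-fold ncRNA/coding contrast cannot coexist with a 0.05 coding fraction
  inside [0, 1], so ncRNA saturates near full coverage instead (realized
  fold ~18). This is a representational limit of the coverage-fraction
  statistic, not of the generator.

What the generator does *not* emulate: overdispersion (counts are pure
Poisson; real NET-seq libraries are noisier), mappability structure, sequence
content (no motifs — binding-site placement is positional only), copy-number
variation in repeats, and replicate batch effects. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not performance on real libraries.

All generators are deterministic given (seed, stream, genotype/role,
replicate), using independent `SeedSequence` streams per assay.

## Problem sizes used for self-validation

Recovery runs use: 400 planted pauses (200 dependent / 200 independent) in a
190-kb repeat region for peak calling, classification and dwell analysis;
~310 genes on a 1.5-Mb chromosome for traveling ratios; and 20 null plus 20
spiked 300-kb genomes (one 3–15-kb domain at 4–6× each) for PIER specificity
and recall. These sizes give stable rates (binomial noise ≤ ~1–2 percentage
points on the recovery estimates) while keeping a full validation run in
seconds.

## Known limitations

- The genome-wide region partition for pause calling must be supplied by the
  caller (per fragment or per transcript); no default genome-wide partition
  is defined.
- The Pearson chi-square p-values are df=1 asymptotic survival values; for
  the small isolate tables an exact test would differ slightly (the
  statistic, not the p-value, is the primary surface).
- KS p-values are asymptotic; at sample sizes below ~20 per group they are
  conservative.
- PIER calling assumes one WCE per comparison and broad domains; sharp
  TF-style peaks, spike-in normalization and replicate-consistency (IDR)
  workflows are out of scope.
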