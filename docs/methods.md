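# Methods

`csflm` reimplements, as a tested pipeline on synthetic and user-supplied
data, a CSF-vs-plasma cfDNA analysis for non-small-cell lung cancer with
leptomeningeal metastasis (LM): shallow-WGS genomic-instability scoring,
cfDNA fragment-size profiling, filtered variant-profile comparison between
the two liquid-biopsy compartments, and survival association of the
instability score. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Copy-number pipeline

**Binning.** Aligned fragments are counted into contiguous 1-Mb windows
(0-based half-open internally; BED convention on disk), one count per
template at its leftmost mapped coordinate. Sex chromosomes are masked
before any normalization — cfDNA donors of either sex would otherwise
contribute spurious "aberrations". Defaults for the read filters the
upstream description leaves open: MAPQ ≥ 30, duplicates and
secondary/supplementary alignments excluded; both configurable.
Fragment-to-bin assignment by leftmost coordinate (rather than midpoint)
is count-conserving and simpler; at 1-Mb resolution the difference is
immaterial.

**GC correction.** Bin counts are divided by a LOESS fit (statsmodels
`lowess`, `frac = 0.4`) of count on GC fraction over unmasked bins, then
rescaled so the median corrected value equals the median raw count. Bins
whose GC lies outside the fitted support are masked. The correction is
idempotent to < 1e-6 relative and requires ≥ 50 unmasked bins.

**Stable regions.** The normalization baseline is the set of "stable"
chromosomal runs of the germline profile: maximal runs of at least
`min_run = 10` bins whose corrected coverage has coefficient of variation
≤ `cv_max = 0.12` with every bin within `rel_tol = 15%` of the run median,
and whose heterozygous germline SNPs all have |VAF − 0.5| ≤
`vaf_tol = 0.08`. No published thresholds exist for "relatively stable";
these values accept nearly the whole genome of a flat diploid germline at
the depths considered while rejecting 3-fold coverage spikes and
copy-altered regions with skewed allele fractions. All four are
configurable. Stable detection runs per patient; het-SNP VAFs are an
explicit input table regardless of the assay that produced them.

**Normalization.** Each sample's corrected coverage is divided by its own
mean over stable bins, giving a dimensionless representation r_i with
stable-region mean exactly 1, separately for the cfDNA sample and its
matched germline. The per-bin signal is ℓ_i = log2(r_i^sample /
r_i^germline). Bins whose germline representation falls below 0.1 are
masked rather than allowed to blow up the ratio. The whole construction is
invariant to rescaling either sample's counts by any positive constant.

## Segmentation

Per chromosome, over unmasked bins only (a masked gap never splits a
segment's bookkeeping), a CBS-style recursion fits the piecewise-constant
model: the candidate change maximizing a two-sample t-like statistic is
accepted iff its seeded permutation p-value (values permuted within the
current segment, `n_perm = 1000`) is below `alpha = 0.01`, and recursion
continues on the resulting pieces.

Two numerical choices deserve note:

* **Circular vs binary statistic.** For segments of ≤ 60 bins the
  candidate set is every arc [i, j) tested against its complement (the
  circular statistic of CBS proper, O(n²) candidates); above 60 bins the
  candidate set is the n − 1 binary splits. A short high-amplitude
  interstitial event flanked by similar levels has a weak best *binary*
  split — the arc statistic is what detects it — while for the
  megabase-scale events relevant to LST counting on ~100–250-bin
  chromosomes the two have equivalent power and the binary scan is far
  cheaper.
* **Strict-inequality permutation p.** The p-value counts permutations
  whose maximal statistic strictly exceeds the observed one. For
  continuous data this coincides with the usual ≥ convention almost
  surely; for discrete-valued profiles, ≥ would count arrangements that
  merely tie the observed optimum as evidence against it.

On noiseless piecewise-constant input a constant segment has statistic
exactly 0 and can never split, so false boundaries are impossible there;
`alpha` then only limits detection, which is why oracle-style checks in
the test suite run at 0.05 while 0.01 remains the default for noisy data.
With the permutation resolution of `n_perm = 1000` the smallest achievable
p is ≈ 0.001. No undo/merge heuristics are applied at this stage; the
smoothing step below owns small-segment cleanup. Results are reproducible
run-to-run through the seeded permutation RNG.

## Instability scores

**Smoothing.** Small-scale copy-number variation is filtered before
counting: iteratively, the shortest segment under `min_len = 3 Mb` is
removed — its bins extend the flanking neighbor whose mean is closer, but
they are *excluded* from that neighbor's mean, so a small event cannot
drag the surrounding copy state; then adjacent segments whose means differ
by less than `merge_delta = 0.1` log2 units are merged (bin-weighted over
the bins still backing each side), to a fixed point. Keeping absorbed bins
out of the neighbor mean is what makes the LST count exactly invariant to
sub-3-Mb events interior to a constant region; averaging them in (the
obvious alternative) shifts the neighbor mean by up to δ·s/(n+s) and can
flip boundary decisions. Smoothing is idempotent. A short segment alone on
its chromosome has no neighbor and survives flagged `terminal_remnant`.

**LST.** The large-scale state transition count is the number of
within-chromosome boundaries between adjacent smoothed segments that are
each ≥ `min_flank = 10 Mb` long and differ in mean by ≥ `min_change = 0.1`
log2 units. Chromosome ends never count. `min_change` quantifies the
"change in coverage" a breakpoint needs; 0.1 sits above the shallow-WGS
log2 noise floor at the depths considered and is configurable. Counting is
per chromosome (not per arm); with arm annotations a user can pre-split
chromosomes in the genome layout to obtain arm-aware counts.

**GIN.** The genome instability number is

    GIN = Σ over unmasked autosomal bins of 100 · | r_i − E |,

where r_i = r_i^sample / r_i^germline and E is the mean of r_i over stable
bins. The ×100 scale and the stable-region expectation are this package's
definition choices — the quantity is defined up to an arbitrary scale, and
all tests of it are scale-robust (zero on identity, exactness on single
deviations, linearity under deviation scaling, invariance to count
rescaling). Absolute GIN values are therefore comparable within this
package only.

## Fragment-length profiling

Histograms cover 20–600 bp, one count per properly-paired template via the
absolute template length. The short-fragment fraction is the mass on the
closed range 20–150 bp. The modal length is located after a 3-bp
moving-average smoothing (ties broken toward the tallest raw bin); a mode
under 160 bp flags a short-shifted, ctDNA-enriched sample. Paired
CSF/plasma statistics are compared with the two-sided Wilcoxon signed-rank
test: zero differences dropped, exact sign-permutation null for n ≤ 25,
normal approximation with continuity correction beyond, and p = 1 for the
degenerate all-tied case.

## Variant comparison

Calls are kept when VAF ≥ 0.1%, unique-read support ≥ 4 and the call is
not germline, then restricted to the 84-gene panel shared by the capture
designs. The packaged gene list is a synthetic stand-in of well-known
lung-cancer genes (the vendors' shared design is not public) and is meant
to be replaced via `--panel`. Cross-compartment matching is by exact
nucleotide change — (gene, nt change) for small variants, (gene,
direction) for gene-level CNVs — so the same protein change reached
through different substitutions in the two compartments counts as
compartment-private, which is the biologically meaningful reading when
resistance mutations arise independently on either side of the blood–brain
barrier. A somatic VAF strictly above 50% flags likely loss of
heterozygosity.

## Survival association

Patients are split at the sample median of their LST scores; ties at the
cutoff go to the high-instability group. Kaplan–Meier estimation and the
two-group log-rank test are delegated to lifelines behind this module's
interface; hand-worked product-limit and log-rank tables serve as
independent oracles in the tests. The KM median is the smallest time with
S(t) ≤ 0.5 (undefined if the curve never crosses); fixed-horizon rates
(default 6 months) are read off the right-continuous step function.
">"-prefixed follow-up times in the clinical table are right-censored at
the stated value.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with recorded
ground truth, under seeded determinism:

* **Binned coverage.** Expected count in bin i is
  `depth · exp(g·(gc_i − 0.5)) · [(1 − tf)·2 + tf·cn_i]/2`, drawn
  negative-binomially with variance `μ(1 + d·μ)`. Defaults: depth 10,000
  fragments/bin (~3× WGS, PE150, 1-Mb bins), GC-bias slope g = 1,
  dispersion d = 0.003 (≈ 5–8% bin CV, typical of GC-corrected shallow-WGS
  bins), tumor fraction 0.6 (consistent with the high driver VAFs seen in
  CSF). The recorded true LST count comes from an independent scan of the
  segment specification (absorb < 3 Mb runs, count ≥ 10 Mb flanks).
* **Het SNPs** every 0.5 Mb: VAF ~ N(0.5, 0.02) in balanced regions,
  ~0.05/0.95 inside germline-aberrant spans.
* **Fragment lengths** from a two-normal mixture, modes 145 and 167 bp
  with σ = 10 bp — the qualitative short-tumor vs mononucleosomal contrast,
  not a claim about any cohort's exact densities.
* **Paired variants** with exact shared/CSF-only/plasma-only counts; every
  generated call passes the default filters, so the partition sizes are
  recoverable ground truth.
* **Survival**: exponential event times with the requested group medians;
  censoring times uniform on (0, c_max) and independent of the event
  times, with c_max solved so the expected censored fraction matches the
  requested rate (censoring at a uniform fraction *of* the event time —
  the tempting shortcut — is informative and biases the KM median upward,
  which is why it is not used).

What the generator does not emulate: mappability and blacklist artifacts,
replication-timing waves, centromeric/telomeric structure, subclonal
heterogeneity, fragment-level positional biases, and sequencing-error
variant calls. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated noise model, not robustness to
every artifact of real shallow-WGS data.

## Problem sizes and test design

Simulation-based checks use a 4-autosome × 120-Mb synthetic genome (480
bins) — large enough to hold six ≥ 10-Mb-flank transitions and realistic
chromosome-scale segmentation, small enough for tens of replicates per
check. Recovery checks run 50 replicates at depth 300/bin and tumor
fraction 0.8 (and 0 for the null); survival recovery runs 100 replicates
of 500 patients per group. Oracle equivalences (exhaustive RSS
segmentation, Wilcoxon sign-pattern enumeration, brute-force LST re-scan)
use exact enumeration at small n. In recovery checks the "within 10%"
criterion for KM medians applies to the replicate-aggregated medians; the
per-replicate sampling error of a KM median at n = 500 is of the same
order as the bound itself.

## Known limitations

* Absolute GIN values are package-specific (scale choice above); only
  relative comparisons within a consistently-processed cohort are
  meaningful.
* No tumor-fraction/ploidy deconvolution: log2 shifts are attenuated by
  (1 − tf), so LST sensitivity degrades at low tumor fraction — by design
  the statistic is read against fixed thresholds, not rescaled.
* No mappability/blacklist correction; heavily artifact-prone regions
  should be masked upstream or excluded via the layout.
* The segmentation permutation test controls per-decision error, not a
  genome-wide rate; with ~6 accepted segments per genome at alpha = 0.01
  an occasional spurious split survives smoothing (observed as a few
  percent of recovery replicates missing the planted count by one).
* The packaged 84-gene panel is a placeholder; conclusions about specific
  genes require the user's actual panel.
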