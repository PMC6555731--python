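# Methods

## Scope and data model

The package quantifies three independent readouts of myotube maturation:
transcriptomic gene-set shifts, sarcomere periodicity in fluorescence line
profiles, and contractile-protein band ratios from gel densitometry. Each
readout consumes a small, explicit data container (`LfcTable`, `GeneSet`,
`IntensityProfile`, `LaneProfile`) validated at construction, and each has a
synthetic generator that plants a known truth so the estimator's bias and
noise behaviour can be measured directly.

## Gene-set shift statistics

**Model.** For a comparison between two conditions, each gene carries one
log2 fold change. A gene set's shift is the difference between the set's
median LFC and the background's median LFC. Two background conventions are
implemented: *all genes* (the default, used for the reported statistic) and
*complement*. For small sets the two nearly coincide (checked at a 1% set
fraction in the tests); with several large planted sets in one table only
the complement version is unbiased for the planted shift, because shifting
many genes moves the all-genes median itself. Medians of even-sized samples
are the midpoint of the two central order statistics.

**Inference.** The Wilcoxon rank-sum test always compares set against
complement so the two samples are disjoint. The null distribution of the
rank sum is enumerated exactly by dynamic programming when
`n_set * n_complement <= 400` and no ties are present; otherwise a normal
approximation with tie correction and a 0.5 continuity correction is used.
The two-sided p-value is `min(1, 2 * min(P(W <= w), P(W >= w)))`. Both
branches match scipy's Mann-Whitney implementation to machine precision and
the exact branch matches brute-force subset enumeration; those comparisons
live in the tests, not in the implementation.

**Set derivation and filtering.** In vivo up/down sets come from a
developmental DE table as `{q < 0.05, LFC > 0}` and `{q < 0.05, LFC < 0}`;
genes with LFC exactly 0 join neither. The q threshold is configurable —
0.05 is the package-wide significance convention. "Expressed" means
TPM >= 1 in at least one sample, both configurable; this is a modelling
choice, since expression cutoffs are a matter of convention. Gene matching
is exact string match after whitespace stripping; set genes absent from a
table are dropped and counted, never imputed.

**Z-score.** A single shift value is located within a reference group via
`z = (value - mean) / sd` with the sample (n-1) standard deviation and a
two-sided normal p-value. Sidedness and the sd convention are deliberate
package choices and are stated here because other conventions exist.

## Sarcomere period estimation

**Estimator.** The profile is mean-subtracted (rectangular window by
default, Hann optional), zero-padded to the next power of two at or above
4x its length, and the FFT magnitude spectrum is searched for local maxima
at frequencies within [1/max_period, 1/min_period], default periods
1.6-3.4 um — the physiological sarcomere-length range. The winning peak is
refined by parabolic interpolation over its two neighbouring bins and
inverted to a period. On a noiseless 15-period profile this yields period
errors around 1e-4 um; the dominant error under noise is the peak's
stochastic displacement, with mean absolute error ~1e-3 um at a noise SD of
half the amplitude (100 seeds, tested).

**Absence criterion.** A period is reported absent unless (a) the in-band
peak exceeds twice the median in-band magnitude (the prominence factor,
configurable) and (b) the peak dominates the spectrum over the
neighbourhood of periods [min_period/2, 2*max_period]. Criterion (b) exists
because a strong periodicity just outside the search window leaks a skirt
into the band that can pass the median test alone; restricting dominance to
a neighbourhood keeps slow intensity trends (periods > 2x the window
maximum) and fine texture from masking a genuine sarcomere peak. The
reported `peak_power` is the peak-to-median-magnitude ratio, which makes it
invariant to intensity scaling and offsets.

**Line profiles from images.** Profiles are sampled at unit-pixel spacing
along a segment with bilinear interpolation (pixel centers at integer
coordinates, x right, y down, 0-based); the profile's physical spacing is
the pixel size times the per-sample step. Oblique sampling recovers planted
periods within 2% in the tests.

**Striation series.** Peaks are detected with prominence >= 25% of the
profile's amplitude (max - min). The reported run is the longest contiguous
block of peaks whose successive spacings all lie within +/-25% of that
block's median spacing (an O(n^2) scan over windows, exact for the profile
sizes involved); a myotube qualifies as sarcomeric when the run reaches 15.
The prominence fraction, spacing tolerance and threshold are configurable:
the series criterion automates what is, at the bench, a visual call, and
should be read as a proxy rather than a replica of human annotation.

**Group statistics.** One-way ANOVA (`scipy.stats.f_oneway`) with Tukey HSD
(`scipy.stats.tukey_hsd`). Two groups with identical constant values give
F = 0, p = 1 by convention; all-equal within-group values with unequal
means give the F -> infinity, p -> 0 limit.

## Gel densitometry

**Baseline.** The baseline is a morphological opening (rolling minimum then
maximum, structuring element of half-width `radius` samples, boundary mode
nearest) *recentred by the median of the raw residual*. The recentring
matters: on noisy lanes a plain opening follows the noise minima and sits
roughly 2.3 noise-SDs below the true baseline (the expected minimum of ~80
Gaussian draws), and that per-sample offset, integrated over a band window,
overwhelms small bands. The median of the residual is an unbiased estimate
of the offset under symmetric noise because bands occupy a minority of the
lane. Residual negatives are clipped to zero after subtraction.

**Quantification.** Band totals are plain sums over fixed half-open index
windows; lane total is the sum over the whole background-subtracted lane;
fractions and ratios follow. Windows of +/-3 band-SDs capture 99.7% of a
Gaussian band while keeping the integrated clip bias small; with noise at
10% of the taller band's peak height, a planted 3:1 amount ratio is
recovered within 10% (mean over 100 seeds, tested). All intensities are
arbitrary units; only fractions and ratios are interpreted, as in
stained-gel practice.

**Ladder calibration.** Least-squares fit of log10(MW) against migration
position, rejected if the ladder is not strictly monotone; queries outside
the fitted MW range are flagged as extrapolations.

## Synthetic data: what it emulates, what it does not

LFC tables draw background genes from N(0, sigma^2) and set genes from
N(delta, sigma^2) with disjoint identifier ranges; the default sigma = 0.3
is a modelling choice (observed LFC dispersions vary by pipeline and
comparison and no single value is canonical), and delta defaults follow the
effects the analyses are designed to detect (0.1 for the 198-gene
sarcomere set; 1.4 for the 87-gene in-vivo set in the strongest,
primary-myotube-like comparison). Striation profiles are pure cosines plus
white Gaussian noise; lanes are Gaussian bands on a flat baseline.
Developmental DE tables plant exact counts of significant genes (143 up,
78 down by default) with q-values uniform within their stratum — q
magnitude carries no information beyond the threshold.

Real data differ in ways the generator deliberately ignores: LFC
distributions are heavy-tailed and gene-gene correlated; sarcomere
striations drift in phase, decay in amplitude and sit on uneven
illumination; gel baselines curve and bands skew. Passing tests therefore
demonstrate estimator correctness and calibration under the stated model,
not robustness to every artefact of real measurements. The test-suite
sizes (200 tables for shift recovery, 100 seeds for period and band
recovery, 2000 simulations for test-size checks) were chosen to make
Monte-Carlo error comfortably smaller than the tolerances being checked.

## Pipeline and reproducibility

Every generator takes a mandatory seed and is a pure function of its
config; there is no global random state. The pipeline derives per-output
seeds from the run seed by fixed offsets, so a fixed config yields
byte-identical TSV/CSV/JSON outputs across runs (timestamps live only in
the manifest). Malformed TSV/GMT inputs raise named parse errors with file
and line; dropped set genes are logged with counts, never silent. The CLI
exposes each stage as a subcommand over the same YAML config and exits
nonzero with the error class named on stderr.

## Known limitations

- The FFT estimator assumes a single dominant period; profiles spanning two
  sarcomere populations return one blended peak.
- The series counter's spacing tolerance (25%) and peak prominence (25% of
  amplitude) were fixed by inspection of the synthetic profiles; heavily
  textured real images may need retuning.
- Densitometry assumes bands are separated by more than the structuring
  element; overlapping bands (e.g. MyHC isoform doublets) are integrated
  as one.
- The Z-score comparison treats the C2C12 group as normally distributed;
  with very few group members the p-value is indicative, not exact.
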