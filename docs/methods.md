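# Methods

## The V-plot representation

A paired-end ATAC-seq fragment is summarized by two numbers: the genomic
position of its midpoint and its length.  Around a fixed 640-bp window the
fragments form a 2-D histogram — the V-plot — with 5-bp genomic bins along
the window (W = 128 columns) and 10-bp fragment-size bins up to 640 bp
(H = 64 rows).  Size bin j covers lengths 10j+1 … 10j+10, so bin 0 holds
1–10 bp and bin 14 is the last bin entirely below 150 bp.  Fragments whose
midpoint falls outside the window or whose length exceeds 640 bp are
ignored.  The counts in each genomic-bin column are normalized to sum to
one; all-zero columns are left at zero rather than imputed.  The midpoint
convention (rather than fragment endpoints) is what produces the "V"
geometry: nucleosome-protected fragments of increasing length sit
symmetrically around the dyad.

Coordinates are 0-based half-open (BED convention) throughout.  Analysis
windows are anchored so that the site of interest (dyad, NFR center, motif
center) is the window midpoint: region = center ± 320 bp.

## The conditional variational autoencoder

For each region, the V-plot densities of the S samples are stacked on the
channel axis, x ∈ R^{W×H×S}.  A per-sample latent Gaussian z ∈ R^{K×S}
(K = 5) captures the region's chromatin state; the sample indicator s is
treated as a nuisance covariate that carries the library's fragment-size
profile.  Conditioning enters twice:

* a trainable embedding maps each sample index to a fragment-size offset
  vector g ∈ R^{H} that is broadcast along the genomic axis and added to
  that sample's input channel;
* the decoder receives the latent vector concatenated with the one-hot
  sample indicator.

The encoder is four convolution blocks (16 filters, 3×3 kernel, stride 2,
batch normalization, ReLU), which reduce the 128×64 plane to a 8×4
bottleneck; a dense head emits the posterior mean (K×S) and log-variance.
By default the posterior standard deviation is per-sample (K×S); a
`shared_sigma` mode reduces it to a single K-vector shared across sample
channels.  The per-sample default makes the two-sample test below
well-defined for every pair.

The decoder maps (z, one-hot s) through a dense layer to a 128-vector,
reshaped to 4 channels on the 8×4 bottleneck grid, then through four
transposed-convolution blocks mirroring the encoder.  The final block
emits a single channel with no batch-norm/ReLU, feeding a softmax over the
fragment-size axis of each genomic bin, so every column of the estimated
V-plot sums to one and all entries lie in (0, 1).

Training maximizes the ELBO: pixel-wise binary cross-entropy between the
input densities and the softmax output (predictions clamped to
[1e-7, 1-1e-7] before the logs), plus the closed-form KL of the diagonal
Gaussian posterior against the standard normal prior,
½ Σ (μ² + σ² − 1 − log σ²).  One Monte-Carlo sample z = μ + σ⊙ε per region
per step (reparameterization trick), Adam at a peak learning rate of 0.01
with linear warmup followed by cosine decay.  Defaults: batch size 64,
100 epochs, 100 warmup steps, KL weight 1.  The loss reported per epoch is
the mean per-region loss (BCE summed over pixels and samples + KL).

The network layers are implemented in numpy, with the 3×3/stride-2 gather
and scatter kernels jit-compiled by numba; the transposed convolution is
the exact adjoint of the strided convolution.  All layer gradients and the
full training-step gradient are verified against finite differences in the
test suite.  Given (seed, data, config), initialization, shuffling and
noise draws come from one `numpy` generator, so training histories are
bit-reproducible on a single-threaded run.

Batch-free estimated V-plots encode with the true sample indicator and
decode every sample's posterior mean under a fixed reference indicator s0
(sample 0 by default).  Batch normalization uses running (inference)
statistics at that point.

## Statistics

**Differential V-plot test.**  For one region and samples (a, b) with
posterior means z_a, z_b and standard deviations σ_a, σ_b:

    Q = Σ_k (z_ak − z_bk)² / (σ_ak² + σ_bk²),

referred to a χ² distribution with K degrees of freedom (upper tail).
Multiple testing uses Benjamini–Hochberg.

Calibration caveat: under a true null (two independent down-samples of the
same pool, jointly encoded), Q is strongly *under*-dispersed relative to
χ²_K, so p-values pile up near 1 and their distribution is far from
uniform.  Two effects compound: the posterior σ measures latent
uncertainty, which exceeds the sampling variability of the posterior mean
(for any Bayes-consistent model the ratio Var(μ_a − μ_b)/(σ_a² + σ_b²) is
below 1 and shrinks as observation noise grows), and the shared encoder
sees both channels at once, correlating μ_a and μ_b so their difference
cancels further.  Longer training sharpens reconstruction and makes the
test *more* conservative, not less.  The test is therefore a ranking
statistic, not a calibrated frequentist test: ordering regions by p
separates shifted from unshifted regions with AUC ≳ 0.99 while the same
ranking on null comparisons is indistinguishable from chance (AUC ≈ 0.5).
Detection thresholds (adjusted p < 0.05) should be read as conservative.

**Nucleosome scores.**  On a batch-free estimated V-plot the central NFR
weight w averages, over the N = 20 genomic bins whose centers lie within
±50 bp of the window center, the per-column mass in the M = 15 size bins
below 150 bp.  The default normalization divides by N only, so w ∈ [0, 1]
("column_fraction"); a "literal_paper" mode divides by N·M, which bounds w
by 1/M and would squeeze the nucleosome score into [1 − 1/M, 1], making
absolute thresholds like Nuc > 0.5 vacuous — the two modes differ by the
constant factor M and rank regions identically, so all AUCs agree exactly
between them.  The central nucleosome score is Nuc = 1 − w, floored at
ε = 1e-3; the differential score between samples i and j is
δ = ln Nuc_j − ln Nuc_i (natural log), positive when chromatin closes.
A site is called *more accessible* in sample j when the BH-adjusted
p-value is < 0.05 and δ < −0.2, *less accessible* when δ > 0.2 instead.

Bin-geometry choice: "within 50 bp of the center" is measured to bin
centers (±2.5 … ±47.5 bp → 20 bins); measuring to bin edges would give 21.

## The simulator

The simulator provides the ground truth that real data lacks.  One
synthetic contig (defaults: 200 kb) carries dyads spaced
Normal(200 bp, 20 bp) apart; 100 disjoint 300-bp nucleosome-free intervals
are carved out, removing any dyad whose 147-bp core would touch them.
Fragments are drawn from a four-class mixture following the canonical
ATAC-seq fragment-size groups — NFR < 100 bp (shifted truncated
exponential), mono 180–247 bp, di 315–473 bp, tri 558–615 bp (truncated
Gaussians with means ≈ 200/394/586 bp).  Mono fragments center on a dyad,
di/tri on the midpoint of 2/3 consecutive dyads (runs broken by a carved
NFR are excluded), all with Gaussian positional jitter (sd 20 bp); NFR
fragments center uniformly inside an NFR interval.  Default mixture
weights (0.45, 0.35, 0.15, 0.05) put >95 % of reads in the four canonical
groups, as in deeply sequenced ATAC-seq libraries.  Lengths in the gaps
between groups get zero weight by default so class identity stays
unambiguous for testing.  The batch panel used in the correction
experiment varies the weights and the mono-peak position/width across
samples (e.g. mono means 192/205/220 bp), emulating library-to-library
fragment-size variation.

What the simulator does **not** model: sequence context and Tn5 insertion
bias, GC bias, mappability, overlapping/fuzzy nucleosomes, chromatin
heterogeneity within a sample, and real inter-sample biology.  Passing the
benchmarks therefore shows that the model recovers positional/size
structure from sparse counts under realistic fragment-size mixtures — not
that it resolves every complication of real chromatin.

## Benchmark designs and problem sizes

All benchmarks run end-to-end (simulate → bin → train → score) on one CPU
in minutes; sizes were chosen as the smallest that leave the read-outs
stable across seeds.

* **Shift detection.**  A 200-kb contig at ~1 fragment/bp; two independent
  10 % down-samples (datasets #1, #2) and 3′-shifted copies of #2.  550
  tiled 640-bp windows with ≥5 reads per sample; one model over all
  datasets (20 epochs).  Read-outs: AUC of ranking shifted vs unshifted
  comparisons by −log10 p; the null p-value distribution (see caveat
  above) and its chance-level label AUC.
* **Nucleosome recovery.**  A 600-kb contig with 250 NFR intervals; 250
  dyad-centered and 250 NFR-centered windows; down-sample fractions 1 %,
  10 %, 100 % with three independent down-sample replicates stacked as the
  model's samples (15 epochs); AUC of ranking dyads above NFR centers by
  Nuc, averaged over replicates.
* **Nucleosome change.**  Condition B converts half of condition A's 250
  NFR intervals to nucleosome-occupied (a dyad appears at the interval
  center); both conditions down-sampled to 10 %; one two-sample model
  (20 epochs); AUC of ranking converted above unchanged sites by δ, and
  the median δ at converted sites (positive = closing detected).
* **Batch correction.**  Three samples from the batch panel on one truth;
  300 tiled windows; mean pairwise L1 distance between per-sample
  aggregated fragment-size profiles of the raw inputs vs the batch-free
  estimates.

## Numerical and degenerate-input conventions

* All-zero V-plot columns stay zero through normalization; the BCE loss
  compares the softmax output against them without masking.
* Posterior σ uses an exp(½ logvar) parameterization and is strictly
  positive; a zero σ entering the Q statistic is a validation error.
* δ is protected from −∞ by the ε floor on Nuc.
* ROC AUC uses the Mann–Whitney form with ties counted ½.
* Down-sampling draws exactly round(fraction·n) fragments without
  replacement; 3′ shifts translate whole fragments, preserving length
  (shifting each mate along its own strand would change lengths and
  confound the positional signal the benchmark isolates).
* Fragment-size bin floor((length−1)/10) makes bin boundaries inclusive on
  the right (…−10 bp belongs to the first bin).

## Known limitations

* The differential test ranks well but is not calibrated under the null
  (see above); reported p-values are conservative.
* One model is trained per analysis over its S samples jointly; there is
  no transfer across datasets.
* The numpy/numba implementation is desk-scale: hundreds to a few
  thousand regions per minute of training on one CPU, not genome-wide
  peak atlases.
* Upstream read processing (alignment filtering, duplicate removal, Tn5
  +4/−5 offset) is assumed done; inputs are fragment interval files.
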