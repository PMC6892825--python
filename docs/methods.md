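# Methods

This note documents the models, conventions and numerical choices behind
`mslab`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, which
knobs matter, and what the synthetic validation does and does not show.

## 1. Signal model and preprocessing

A recording is a C × T matrix of scalp potentials (µV) with sampling rate
fs, channel names, unit-sphere electrode positions and a reference flag.
The default montage is the 19-channel clinical 10–20 layout, taken from
MNE's template montage, re-centred and projected to the unit sphere (a
spherical montage is sufficient for both spline interpolation and
synthetic topography generation; no individual head geometry is modelled).

Filtering uses windowed-sinc (Hamming) linear-phase FIR kernels applied
with group-delay compensation and reflection padding, so filters are
zero-phase and length-preserving. The number of taps follows the Hamming
rule ≈ 3.3 · fs / transition-width; the default transition width is 2 Hz
(at 1 kHz: 1651 taps). Wider transitions shorten the kernel and reduce
temporal smearing at microstate boundaries; 2 Hz matches common EEG
practice for a 2 Hz low edge. Bands: 1–70 Hz band-pass plus 45–55 Hz
band-stop for conditioning, 2–20 Hz for microstate analysis. The 2–20 Hz
filter is applied to the continuous data rather than to individual 1-s
epochs — a kernel longer than one second cannot meaningfully filter a
1-s segment.

Epoch screening replaces visual artifact inspection with a peak-amplitude
rule: a channel is bad within an epoch when its absolute peak exceeds
100 µV (configurable). Epochs with ≤ 2 bad channels have them rebuilt by
spherical-spline interpolation (Perrin construction: order-4 Legendre
weights, series truncated at 50 terms, diagonal regularisation 1e-5,
solved with the sum-to-zero constraint and constant term); epochs with
≥ 3 bad channels are dropped. "Fewer than three" is read as ≤ 2
interpolated / ≥ 3 rejected. Subjects keep their data only with ≥ 30
surviving epochs. Surviving epochs are concatenated into one continuous
record; the seam indices are retained, but segments are *not* split at
seams during back-fitting (a configurable sensitivity flag exists).

## 2. Microstate segmentation

GFP(t) is the spatial standard deviation across channels (equal to the
RMS under average reference). Peaks are local maxima with ≥ 10 ms
separation; peaks whose GFP exceeds mean + 2·SD of the GFP-at-peak
distribution are discarded (the exclusion is centred on the mean of the
peak distribution — the bare phrase "exceeds two times the SD" is
ambiguous about centring, and mean + 2·SD is the reading that actually
removes outliers). Peak topographies are pooled across subjects with a
per-subject cap equal to the smallest subject's peak count, so long
recordings do not dominate the templates.

TAAHC (topographic atomize & agglomerate hierarchical clustering) starts
from singleton clusters and repeatedly (i) finds the cluster with the
lowest GEV contribution Σ (a_p · |corr(u_p, proto)|)² over its members
(a_p the peak GFP), (ii) dissolves it, (iii) reassigns each freed map to
the surviving cluster of highest polarity-invariant correlation, and
(iv) updates the affected prototypes as the polarity-aligned first
principal component of the member maps, until K clusters remain. The
"worst cluster" criterion and the PC prototype follow the convention of
the established microstate toolboxes; sum-of-|correlation| is available
as an alternative criterion (`worst_criterion="abs_corr_sum"`). Since
member maps are zero-mean across channels, prototypes remain
average-reference consistent by construction.

All similarity is polarity-invariant: r = |Pearson correlation across
channels|, and the global map dissimilarity satisfies GMD² = 2(1 − r)
(an identity the test suite verifies against both implementations).
Estimated maps are matched to canonical archetype geometries by Hungarian
assignment on the |correlation| matrix and labelled A–D(–E, F).

Back-fitting labels every sample (not only GFP peaks) with its
best-correlated template. Temporal smoothing then relabels any run
shorter than 30 ms to each sample's next-best class, processing
left-to-right and iterating; ties break toward the lower class index.
Two details are deliberate deviations from the naive rule, both needed
for a well-defined fixpoint:

- classes a sample has already held during smoothing stay excluded for
  that sample (otherwise a 1-sample run wedged between two long runs of
  other classes oscillates between its best and second-best class
  forever);
- a sample that has walked through its entire ranking merges into the
  neighbouring run.

With these, the procedure provably terminates with no sub-threshold run
(the only exception is a degenerate input shorter than the threshold
itself), while reducing to "relabel to the runner-up" in the ordinary
case of isolated short runs.

GEV = Σ_t (GFP_t · r_t)² / Σ_t GFP_t², with a per-class partition that
sums exactly to the total. It is scale-invariant and lives in [0, 1].

## 3. Features, syntax and group statistics

Per subject and class: duration = mean run length (ms), occurrence =
runs per second, coverage = labelled-sample fraction; the three satisfy
duration × occurrence / 1000 = coverage exactly when computed from one
label sequence. Classes absent from a sequence get duration 0 and a
`present=False` flag rather than NaN.

Observed transition probabilities count changes between consecutive
distinct runs, normalised by the total transition count (diagonal
structurally zero). Expected probabilities under the occurrence-only null
are E_ij = p_i p_j / Σ_{k≠l} p_k p_l with p the normalised occurrence —
independence with self-transitions excluded, the standard syntax-analysis
null. The chi-square distance Σ_{i≠j} (O−E)²/E compares the two, and a
permutation test swaps each subject's observed/expected pair with
probability ½ per repetition (5000 by default), preserving within-subject
pairing. The p-value uses the add-one estimator (1 + #{T* ≥ T})/(1 + B),
which cannot return 0. The test is run per group by default; a pooled
variant is available by passing all subjects' tables at once.

Group inference: two-sided Wilcoxon rank-sum (exact enumeration when both
groups have ≤ 10 untied observations, otherwise the tie-corrected normal
approximation); ANCOVA as OLS of log(feature) on a group indicator plus
age and gender, reporting the group-coefficient t and its two-sided p
(natural log; inference is base-invariant); constant covariates are
dropped with a flag rather than crashing the fit; no multiple-comparison
correction (the design is exploratory, and the companion summary table
reports all 12 feature p-values side by side). Spearman's rho uses
average ranks and the t-approximation p.

## 4. The synthetic cohort generator

The generator emulates the study population the pipeline targets: two
groups (10 DS, 15 DS-AD), 19-channel average-referenced EEG at 1 kHz,
alpha-dominated oscillation whose topography switches among K = 4 planted
template maps, per-subject epoch counts drawn from the published group
distributions (mean 108.3/86.8, SD 57.7/52.9, truncated to [30, 170]),
and metadata (age, gender, DSQIID on [0, 53] as group-conditional
truncated normals with the published group means/SDs).

Label dynamics are semi-Markov: dwell times are gamma with shape 2 and
the group/class mean duration (Table-level group means: DS
65.94/70.79/91.61/81.52 ms, DS-AD 73.19/71.08/89.77/75.79 ms for A–D),
floored at 10 ms; the successor class is drawn proportionally to the
group's occurrence profile with self-transitions excluded. Gamma rather
than exponential dwell times avoid unrealistically memoryless dynamics.

Rendering: v(t) = a(t) · map_{s(t)} + ε(t), where a(t) is a 10 Hz
sinusoid under a slowly wandering positive envelope (white noise
low-passed at 1 Hz, depth 0.5, floored at 0.2, giving ~20 µV GFP at unit
envelope) and ε is Gaussian noise with distance-dependent inter-channel
correlation (squared-exponential on chordal electrode distance, scale
0.7), scaled so the signal-to-noise RMS amplitude ratio equals `snr`
(default 4). Each sample is average-referenced.

State switches are snapped to the carrier's zero-crossings before
rendering (`align_labels_to_carrier`). This reflects the standard
microstate account — topographies are stable across whole field-power
lobes and flip at field-power minima — and it makes the planted truth
identifiable: a switch placed mid-lobe near a zero-crossing would leave
essentially no trace in the signal, making the "true" boundary position
unrecoverable in principle. The snapped sequence is returned as the
ground truth. Two consequences worth knowing: realized durations are
quantized to the half-period grid (~50 ms at 10 Hz alpha) and are
therefore longer on average than the nominal gamma means (≈ 88–116 ms
realized vs 66–92 ms nominal), and segments squeezed below one
inter-crossing gap vanish. Group *ordering* of durations is preserved.

What the generator does **not** model: eye blinks and EMG artifacts (the
pipeline's ICA-free screening is only exercised by amplitude outliers),
eyes-open segments, drowsiness drift, 1/f background spectra, and
individual head geometry. Passing planted-truth tests therefore
demonstrates correctness of the algorithms under the stated signal
model, not clinical performance on real recordings.

Reproducibility: every subject draws from an independent
`SeedSequence([seed, subject_index])` substream, so changing the cohort
size does not perturb other subjects' data; all outputs are pure
functions of the spec and its seed.

## 5. File formats

Recordings are exchanged as FIF (MNE's native format, double precision)
with a JSON sidecar carrying pipeline metadata (reference state, epoch
seams, annotations); EDF files are read transparently. Among the file
formats the installed stack can both write and read, FIF is the one that
round-trips losslessly. Features, transition tables, maps and the
group-summary table are tidy CSV; figures are PNG.

## 6. Validation scale and runtime choices

The test suite and the acceptance script size their simulations to run
comfortably on one CPU: the full-pipeline planted-truth check uses the
default 25-subject cohort once (≈ 45 s, ~16k pooled GFP peaks through
TAAHC); syntax-test calibration uses 500 simulated datasets × 500
permutations; ANCOVA calibration uses 1000 null datasets of n = 30 and
10 replicates of n = 200 for effect recovery; the planted-direction check
uses 10 label-level cohort replicates (the full-pipeline direction is
additionally verified once in the cohort run). These sizes give
Monte-Carlo standard errors well inside the asserted tolerance bands.
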