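# Methods

`isletmap` implements the functional-mapping toolchain used to characterize
coordinated Ca²⁺ activity and β-cell maturity in pancreatic islets: trace
normalization and EMD-based detrending, activity binarization, co-activity
network inference with a permutation null, hub-cell classification,
bias-corrected Morlet wavelet spectra, and per-cell immunofluorescence
quantification. Because real recordings of this kind are rarely shared, the
package also contains a first-class synthetic-data generator that plants the
structures the analysis is supposed to find (hub cells, LOW/HIGH maturity
mixtures), so every stage can be validated against a known ground truth.

## Synthetic islet model

`generate_islet_traces` simulates each cell as a discrete-time Markov
two-state (quiescent/bursting) process on a spatial proximity graph. Cells
are placed uniformly in a disk (`layout_radius`, arbitrary units) and joined
by a symmetrized 4-nearest-neighbour graph. A planted fraction of cells
(`hub_fraction`, default 5%; the study regime is 1–10%) is selected by
farthest-point sampling so hubs are spread across the islet; each hub gains
edges to its nearest `hub_reach_fraction` (default 0.45) of the islet —
making hubs the top-degree nodes by construction — and a multiplicative
influence boost (`hub_boost = 12`).

Per frame, an OFF cell turns ON with probability

    p_on(i) = drive(t) · p_spont(i) + coupling_strength · Σ_j A_ij · w_j · s_j(t−1)

where `w_j` is the influence weight (hub boost or 1) and `drive(t)` comes
from the stimulation protocol (baseline/glucose epochs with drive levels;
KCl epochs force every cell ON, emulating depolarization; "silenced" epochs
multiply `p_on` by their drive level, emulating partial chemogenetic
suppression). ON cells turn OFF with a constant, class-specific rate.

The operating point was chosen once so that the planted structure has the
qualitative signature described for islet hubs — a minority of cells whose
activity repeatedly spans that of the rest of the population:

| parameter | hub | follower | meaning |
|---|---|---|---|
| `p_spont` (at drive 1) | 0.01 | 0.002 | per-frame spontaneous ON rate |
| `p_off` | 0.022 | 0.25 | per-frame OFF rate (≈2.3 s vs ≈0.2 s bursts) |

with `coupling_strength = 0.0015` per edge per frame (the module constant
`REFERENCE_COUPLING`). Hubs emit long bursts and are re-excited by every
local burst group (they are coupled to most of the islet), so they overlap
many groups; followers emit short, jittered bursts recruited mostly by their
nearest hub, so follower–follower co-activity stays near chance. This
separation is what makes the downstream 60%-of-maximum-links rule recover
the planted hubs (mean sensitivity ≈ 0.9, specificity ≈ 0.97 on the truth
raster at n = 50 cells, 120 s).

Fluorescence is `baseline·(1 + drift) + amplitude·state + noise`, with a
slow sinusoidal drift (10% of baseline, ≈100 s period, random phase per
cell) and white Gaussian noise (10% of the burst amplitude). Hub-mapping
recordings are fast (20 Hz), and that is the default frame rate. Noise and
drift magnitudes are not characterized for the original recordings; the
defaults are conventional values for widefield indicator imaging and are
exposed in `IsletSimConfig`.

What the generator does *not* emulate: indicator rise/decay kinetics
(fluorescence follows the state instantaneously), motion and bleaching,
paracrine signalling, electrophysiological detail (no channel models), and
3-D islet geometry. Passing tests therefore demonstrate that the analysis
recovers planted co-activation structure under realistic noise, not that it
is robust to every artefact of real microscopy.

## Trace processing

*Normalization.* `F/F_min` divides each cell's trace by its F_min, taken as
the 5th percentile of the baseline epoch (or of the whole trace when no
epochs are given) — a percentile rather than the literal minimum so that
single-frame dropouts cannot inflate the signal. Ratiometric modes
(Fura-2 340/385, Epac Cerulean/Citrine) return the element-wise channel
quotient.

*EMD detrending.* Each trace is decomposed by classical sifting (cubic
spline envelopes through mirrored extrema, Cauchy SD stop criterion < 0.2,
at most 50 siftings per IMF and 12 IMFs). The baseline trend — the residue
plus any IMF whose mean period (estimated from zero crossings) exceeds half
the record — is removed. By default the fastest IMF is *kept*: at 20 Hz the
short Ca²⁺ transients and the shot noise occupy the same IMF, so removing
"the noise IMF" smears burst timing; the amplitude threshold of the
binarization step rejects zero-mean noise anyway. `noise_rule="imf1"` (drop
IMF 1 always) and `"fast_imfs"` (drop IMF 1 only when its mean period is
below 0.25 s) are available for smoother, heavily oversampled data.

*Binarization.* A frame is ON when the detrended signal exceeds its
baseline by 20% of the trace's dynamic range. The top of the range is the
99th percentile. The baseline anchor is the trace **median**, not the
minimum: a detrended trace is zero-centred and its minimum sits in the
noise/undershoot floor, so anchoring at the minimum fires on noise. The
median tracks the quiescent level provided cells are OFF in more than half
of the frames — the operating regime of islet recordings; for a noiseless
square wave with duty < 50% the ON fraction equals the duty cycle exactly
at any interior threshold. A 1st-percentile anchor remains available
(`baseline_anchor="percentile"`).

*Response metrics.* Amplitude is the stimulus-epoch mean minus the
baseline-epoch mean of the normalized (not detrended) trace; a cell is
responsive when its amplitude exceeds 2 baseline standard deviations (k
exposed in config); pulse duration is the mean contiguous ON-run length of
the raster during the stimulus, and oscillation frequency the ON-run onset
count per stimulus second. These operational definitions are the package's
own, consistent with the binarized framework.

## Co-activity network and hubs

For cells i, j with ON-frame counts T_i, T_j and joint ON count T_ij, the
co-activity coefficient is C_ij = T_ij / √(T_i·T_j) ∈ [0, 1]. Significance
is assessed per pair against a null built by randomizing each binarized row
independently — by default a random circular shift, which preserves each
cell's burst-length autocorrelation while destroying cross-cell alignment
(a full frame shuffle, which inflates significance for bursty traces, is
available as `scheme="full_shuffle"`). The p-value uses the add-one
estimator p = (1 + #{T_null ≥ T_obs}) / (1 + N), N = 1000 by default, so
the smallest attainable p is 1/(N+1). No multiple-testing correction is
applied by default (Benjamini–Hochberg is available but off).

Implementation note: for circular shifts only the *relative* shift of a
pair matters, so the null statistic at permutation k is the circular
cross-correlation of the two rows at lag d_j(k) − d_i(k). The
cross-correlations are computed once per pair by FFT and the permutations
become table lookups — the test is exact per its definition, just fast.
On sparse rasters the discrete null makes the test conservative (observed
false-link rates below α); on dense independent rasters it calibrates to α.

Hubs are cells holding 60–100% of the correlated links. The normalizer is
the maximum per-cell significant-link count in the same islet
(`normalization="max_observed"`): a cell's links can plausibly be a large
fraction of the best-connected cell's, whereas 60% of *all* n−1 possible
links is rarely reached by anyone. Normalizing by n−1 is available. Ties at
the threshold count as hubs; cells with no ON frames are excluded from all
denominators. The hub fraction is hubs over active cells.

## Wavelet spectra

`morlet_cwt` is a Torrence–Compo-style continuous transform: Morlet mother
wavelet with ω₀ = 6, dyadic scales from 2·dt to half the record at 12
sub-octaves per octave (dj = 1/12), FFT convolution with zero padding to
the next power of two. Power is |W|²/scale — the bias correction that keeps
equal-amplitude oscillations at different periods at equal power (without
it, the 20 s tone of an equal 5 s + 20 s pair appears ≈4× stronger). The
cone of influence is the e-folding time √2·s of the Morlet envelope,
expressed as the largest trustworthy period per time point;
`dominant_period` takes the per-time argmax of corrected power inside the
COI and summarizes a window by the median. When a population "mean wave"
is needed (the pipeline's spectral stage), per-cell corrected power is
averaged arithmetically on the common period grid.

## Stain quantification

Segmentation follows the standard recipe: Gaussian smoothing (σ = 2 px) →
auto-threshold → binary mask → connected components with a
distance-transform watershed split (markers ≥ 6 px apart) and a ≥ 20 px
area filter. Per-cell mean intensity is measured on the **unfiltered**
image under the mask (the filter exists only to build the mask, so it
cannot bias means); `intensity_image` lets a mask from one channel measure
another. The default auto-threshold is Li's minimum-cross-entropy method:
with a small bright foreground spanning a wide brightness range (dim LOW
plus bright HIGH nuclei), between-class methods such as Otsu tend to cut
*between* the two nuclear classes and discard the dim population, which is
precisely the population of interest. Otsu, isodata and triangle are
selectable. A blank-field guard additionally requires the threshold to
clear the median background by 5 robust noise SDs, so empty images return
zero cells rather than noise clusters.

Per-cell intensities are mapped to a 0–100 scale by a linear map of the
[p1, p99] of a reference pool (the cells at hand, or an explicit pooled
control group via `pooled_reference` — the appropriate choice when asking
whether a treated islet has lost its LOW population), clipped, and binned
into 21 half-open width-5 bins [0,5), …, [100,105). Cells below 15
normalized units (the bottom three bins) are classed LOW, at or above 15
HIGH; 15.0 itself is HIGH. Note that normalizing a *unimodal* population
against itself necessarily places ≈1–5% of cells near 0; detecting the loss
of a LOW population therefore requires a control reference, as in the
two-group experimental design this mirrors.

CTCF = integrated density − ROI area × mean background fluorescence,
computed exactly; negative values are flagged, not clamped. The qPCR fold
change is 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_case − (Ct_target −
Ct_ref)_control.

## Pipeline and reproducibility

`run_pipeline` executes simulate → process → connect → spectral → quantify
in dependency order, each stage reading only persisted upstream artifacts,
so any stage re-runs identically from intermediates. One global seed fans
out per stage as `(seed·1000003 + stage_index) mod 2³¹`. All floating-point
CSVs are written at 9 significant digits; `summary.json` and every CSV/TIFF
artifact are byte-identical across reruns with the same seed.

## Problem sizes and numerical choices

The validation suite runs islets of 25–50 cells for 90–120 s at 20 Hz
(2 400 frames), 1 000 permutations, and 512² stain images with 60 nuclei —
sizes at which every property is measurable with comfortable Monte-Carlo
margins while a full run takes seconds. Degenerate inputs are handled
explicitly: flat traces binarize to all-OFF; all-OFF cells get C = 0,
p = 1 and are excluded from hub denominators; a cell yielding fewer than
two IMFs passes through detrending with only its residue removed; empty
masks yield empty tables; fully connected islets flag every cell as a hub
(a documented degenerate case).

## Known limitations

- EMD mode mixing on square-pulse-like signals pushes part of the plateau
  content into slow IMFs; the median-anchored threshold absorbs this, but
  recordings whose cells are ON most of the time (duty > 50%) violate the
  anchor's assumption and should use `baseline_anchor="percentile"`.
- The permutation test is conservative on very sparse rasters (discrete
  null); absolute connectivity percentages are comparable only between
  islets analysed with the same scheme and N.
- The hub rule normalized by the maximum observed link count always flags
  at least one active cell in a connected islet; the hub *fraction* is the
  meaningful population statistic.
- Wavelet periods are quantized at 2^(1/12) steps; dominant-period
  estimates cannot be more precise than one scale step.
- The LOW/HIGH classifier assumes the normalization reference spans both
  populations; applied to a unimodal sample without a control reference it
  reports a few percent LOW by construction.
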