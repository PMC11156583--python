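# Methods

This note documents the models implemented in `epimap`, the parameters
that matter, the synthetic data the pipeline is validated on, and the
design choices made where the underlying experimental procedure leaves
them open.

## Event detection on MEA slice recordings

Both detectors share one scheme per channel: optional denoising (linear
detrend, optional 50 Hz notch — off by default), zero-phase band-pass
(second-order Bessel, applied forward–backward with padding of at least
three periods of the lowest corner so edge transients do not leak into
the squared signal), squaring, and z-normalization of the squared
signal over the entire recording. The normalized signal has mean 0 and
SD 1 by construction (tested to 1e-6); all thresholding happens on it.

**Threshold semantics.** User thresholds are expressed in robust
standard deviations of the *band-filtered amplitude* (scale estimated
as median(|y|)/0.6745), the convention of extracellular spike
detection; a threshold *k* corresponds to the cut
((k·σᵣ)² − mean)/SD on the normalized squared signal. Placing *k*
directly on the squared-signal z-scale would make k = 5 equivalent to
only ≈ 2.8 amplitude SDs and bury true spikes under tens of chance
crossings per second at 10 kHz; the amplitude convention keeps the
published-style defaults (IILD 3 SD, MUA 5 SD) usable as-is. The MAD
estimator, unlike the raw SD, is insensitive to the events themselves.

**IILDs** (1–40 Hz band): supra-threshold regions shorter than
`iild_min_dur_ms` (default 40 ms — band-limited noise excursions are
briefer than a quarter period of the band's lower edge, discharges last
hundreds of ms) are discarded *before* merging, then regions closer
than `iild_min_sep_ms` (200 ms, so the two lobes of one biphasic
deflection merge) are joined, bounds are extended to the
half-threshold crossings, and a 0.5 s guard band at each trace edge is
excluded (residual low-frequency power from the reflection padding
otherwise mimics a discharge there). The event peak is the maximum of
the normalized power.

**MUA** (>250 Hz): same scheme; crossings within `mua_refractory_ms`
(1 ms) collapse into one spike. By default only negative-going
deflections count (`spike_polarity="neg"`), matching the dominant
trough of extracellular spikes and halving the chance-crossing rate;
`"both"` restores unsigned detection. At k = 5 the residual chance
rate is ≈ 0.003 Hz per channel, an order of magnitude below the
surround firing rate it must not distort.

**Discharge-versus-spike call**: slow (<40 Hz) and fast (100–500 Hz)
band energies over the event window (filtered within a ±128 ms padded
context); IILD when the slow fraction ≥ 0.5. **Electrode classes**:
IILD+MUA when ≥ 2 discharges, else MUA-only when ≥ 10 spikes, else
silent — the class boundaries are not part of the published procedure
and are exposed as parameters. **Network events**: single-linkage
grouping of discharges whose peaks lie within 50 ms on electrodes that
are 8-neighbors on the grid.

Deviation from acquisition practice: the original recordings used
causal Bessel filters; detection here filters forward–backward so event
times carry no filter delay.

## Synthetic MEA recordings

The generator emulates the activity gradient of a dysplastic slice on a
configurable grid: a contiguous *core* bearing synchronous IILDs and
MUA at 0.74 Hz, a *surround* with MUA at 0.05 Hz, silence elsewhere
(rates from the recorded core/surround contrast; they parameterize the
generator and are then re-measured by the pipeline). Discharges arrive
as a network Poisson process at 2/min, shared across all core channels
with ±10 ms uniform jitter. The high-K⁺ condition multiplies every
MUA rate by 5 and leaves discharge placement bit-identical (the
discharge, spike and noise substreams are split from one seed, so the
control and high-K variants of a seed differ only in spiking).

Waveforms are free parameters (the source recordings quantify neither
amplitude nor duration): spikes are 1 ms negative-dominant biphasic
wavelets at 60 µV; discharges are 300 ms biphasic deflections —
raised-cosine windowed with a decaying envelope so the leading lobe
dominates and the moment of peak deflection is unambiguous — at
150 µV, carrying a Hann-windowed ripple burst drawn uniformly from
100–500 Hz at 15 µV over the middle third. Background is white
Gaussian noise at 5 µV SD. Ground-truth times are the peak absolute
deflection of each inserted waveform.

What this does *not* emulate: 1/f background, electrode drift and
artifacts, spike-amplitude variability and bursting, discharge shape
variability, and MUA locked to discharges. Detector scores on this
data are therefore upper bounds for real recordings; the quantities
the tests pin down are the correctness of the thresholding logic, the
timing conventions, and the calibration of rates.

## Study scale

The validation suite runs the full grid procedure at a reduced scale
chosen to keep each benchmark within minutes on one CPU while leaving
all statistics well inside their tolerances: a 4 × 4 grid (2 × 2 core,
its 8-neighbor ring as surround) and 180 s recordings at the full
10 kHz, 20 seeds. At that scale the surround-rate estimate carries a
3-SE tolerance of ±0.004 Hz, comfortably above the ≈ 0.003 Hz chance-
crossing bias. The generator's defaults (120 electrodes, 600 s) remain
those of the emulated acquisition.

## Histology: cell maps, segmentation, co-labels

**Generator.** Cytomegalic SAβGal⁺ cells are placed by homogeneous
Poisson processes per zone; zones default to vertical thirds of the
field but any shapely geometry can be supplied — the spatial-recovery
benchmark uses the electrode classes' Voronoi regions. Each SAβGal⁺
cell draws all nine panel markers independently with the configured
probabilities (p53 0.92, p16 0.85, SMI311 0.88, VIM 0.95, pS6 0.89,
NeuN 0.98, p21 0.81, nuclear-Hmgb1 loss 0.92, nuclear-LaminB1 loss
0.84). Because a dysmorphic neuron is *counted* as pS6⁺ ∧ NeuN⁺ ∧
soma > 25 µm, the generator places the core and surround populations
at density / (p_pS6 · p_NeuN), so the expected density of the countable
phenotype equals the configured 53.6 and 11.7 cells/mm² while every
co-label fraction stays calibrated. Balloon-cell-like cells are
pS6⁺/NeuN⁻ by definition and confined to a gray–white boundary strip.
Somata rasterize as unit-intensity disks per positive channel plus
Gaussian noise (SD 0.05).

**Segmentation** follows the slide-quantification recipe: fixed
(transferable between groups, the default) or Otsu threshold, optional
watershed from distance-transform peaks, 8-connected components,
discard area ≤ 25 px² (the rule is pixel-denominated and kept so;
physical equivalents depend on the unknown scan resolution, so a µm
gate is available separately through `equiv_diam_um`). Marker
positivity of an object is its mean intensity in the marker channel
against that channel's Otsu cut — a reproducible stand-in for the
original by-eye calls. Co-label fractions carry exact Clopper–Pearson
95% intervals.

**Mutant load.** With a heterozygous variant, each mutant cell
contributes one variant allele in two, so cell fraction = min(1,
2·VAF); VAF > 0.5 is flagged as inconsistent with heterozygosity.
A VAF of 0.42 in microdissected SAβGal⁺pS6⁺ cells versus 0.055 in bulk
maps to 84% versus 11% mutant cells.

## Spatial mapping

Electrode positions are a row-major grid from the top-left electrode
(x by 1,500 µm columns, y by 1,000 µm rows; y increases downward).
Registration is landmark-based affine only, fit by least squares on
≥ 3 non-collinear pairs (exact to < 1e-9 µm RMS when the pairs are
affine-consistent); the original overlays were aligned visually on
anatomical landmarks, so no intensity-based registration is attempted.
Each non-defective electrode claims its Voronoi cell clipped to the
image field; a class region is the union of its electrodes' cells.
Cells are assigned to their nearest electrode — exactly the Voronoi
partition — so counts conserve (no double counting), and density is
count/area in mm⁻². The region rule is a design choice: the published
figure outlines regions by hand without a stated geometry, so only
recovery on synthetic tissue is asserted, not the printed densities.

## Longitudinal EEG

**Detection.** Morlet power (via MNE's `tfr_array_morlet`) on 50
log-spaced frequencies over 1–50 Hz, 7 cycles per wavelet; total band
power in 1 s bins; normalization by median/MAD over the recording —
a plain z-score would let the seizures themselves inflate the baseline
SD (four 20 s bursts in a 10 min trace already push their own z below
any usable threshold), whereas the median/MAD scale is set by the
ictal-free majority of bins. Runs above 6 robust SDs are merged across
gaps < 5 s and kept when ≥ 10 s. The original identification was
semi-automatic with visual confirmation; this is its fully automatic
counterpart with every parameter exposed, and the event table is the
export a reviewer would confirm.

**Generator.** Per-animal baseline daily rates are lognormal around
3/day (dispersion 0.5, matching the order-of-magnitude spread seen
across implanted animals); daily counts are Poisson with the treatment
multiplier applied from the end-of-dosing phase onward; the default
schedule is 14 days pre, 9 days dosing, a 48 h endpoint window, 28
days post. Rendered traces are 0.5–70 Hz band-limited noise with
frequency-gliding (8→4 Hz) bursts at 6× background amplitude under a
Hann envelope.

**Comparison.** Daily frequency is count/hours × 24 per session,
averaged per animal and phase. Phases are compared with the unpaired
exact Mann–Whitney test even though the design is within-animal —
that matches the published analysis choice; a paired alternative would
be a different test and is deliberately not silently substituted.
Quantiles use linear interpolation between order statistics.

## Exact Mann–Whitney test

U is computed by rank summation with midranks. When the pooled sample
is tie-free and C(n₁+n₂, n₁) ≤ 2×10⁵ the null distribution is
enumerated completely; otherwise a seeded Monte-Carlo permutation
(default 10⁵ draws, observed assignment included so p > 0). The
two-sided p doubles the smaller tail and caps at 1 — the rule that
yields the complete-separation floor 2/C(n₁+n₂, n₁), i.e. 0.0286 at
4 vs 4 and 0.0022 at 6 vs 6; an alternative |U − μ|-extremity rule is
available behind a flag. No normal approximation is used anywhere on
the default path. Ties force the permutation path; midrank tie
handling there is a convention choice, documented rather than hidden.

## Numerical and degenerate-input conventions

Times are seconds from trace start, samples 0-based, event intervals
half-open [onset, offset). Constant traces yield empty detections
(zero-variance guard) rather than errors; empty inputs and invalid
parameters raise typed errors (`ConfigurationError`, `ParameterError`,
`InputError`). Sample SD uses n−1; SD/SEM of a single value are NaN,
never 0. All generator randomness descends from one `SeedSequence`
per call; identical config and seed reproduce outputs bit-identically.

## Known limitations

- Synthetic waveforms and noise are idealized (see above); detector
  scores do not transfer to real recordings as-is.
- Affine registration cannot absorb tissue deformation between
  recording and staining; the 400 µm slice is treated as a projected
  2-D field.
- Otsu-based positivity calls assume bimodal marker intensities; weak
  staining degrades gracefully but silently.
- The ictal detector has no artifact rejection (motion, chewing), which
  real EEG requires before thresholding integrated power.
- The VAF→cell-fraction map ignores copy-number changes and impurity
  of microdissection pools.
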