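# Methods

`quasormod` simulates and analyses optical quantal-transmission experiments
at the *Drosophila* larval neuromuscular junction (NMJ): stimulus-locked
single-vesicle release events reported postsynaptically by a synaptically
targeted calcium indicator, super-resolved per-event coordinates, post hoc
structural imaging of active-zone (AZ) proteins (Brp, Unc13A), and the
statistics of octopamine (OA) / phorbol-ester (PdBU) neuromodulation of
per-synapse release probability P_r. This note documents the models, the
parameters that matter, and the design decisions taken where the underlying
experimental procedure leaves the algorithm open.

## The synthetic NMJ

### Geometry

AZs are placed in 1 µm-radius disks along two bouton strings (tonic Ib and
phasic Is motor neurons), with a minimum spacing of 300 nm enforced on the
xy projection — AZs spread along the bouton membrane, so enforcing the
floor in the imaging plane is both the realistic reading and the regime in
which downstream maxima detection can recover every site (spacing enforced
only in 3D admits pairs separated almost purely along z, which no
159 nm-pitch volume can resolve). Axial positions jitter uniformly within
±300 nm.

### Protein content and basal release probability

Per-AZ Brp and Unc13A weights are lognormal and correlated (ρ = 0.7 in log
space, matching the observation that the two scaffold/priming proteins
scale together). Basal release probability follows a power law of Unc13A
content, `basal_pr = 0.05 · (w/w_ref)^γ` (γ = 1) with multiplicative
lognormal scatter (σ = 0.45), then is stretched in log space, if needed, so
the empirical p99/p1 span is at least two orders of magnitude — the
documented range of single-AZ P_r — and clipped to [1e-4, 0.9]. Phasic Is
AZs are 3× stronger than Ib AZs, reproducing their ~3-fold higher basal
quantal density.

The Unc13A lognormal σ defaults to 0.5. This value was set so that the
simulated wild-type drug effects land at the magnitudes the assay reports
(OA boosts Ib quantal density by ~35–40%, PdBU by ~50–60%): a wider spread
pushes most AZs into the dead zone of the modulation sigmoid and shrinks
the population-level boost well below those magnitudes. The
two-order-of-magnitude basal span does not depend on this choice because
the stretch rule enforces it explicitly.

### Modulation model

The drug-induced change in P_r at an AZ with normalized Unc13A content `x`
is

    ΔP_r(x) = gate · s · A / (1 + exp(−(x − x0)·k)) · h + ε

- `A, x0, k` — sigmoid amplitude, midpoint, slope. Two named presets carry
  the published curves: OA vs. normalized Brp (A = 0.04, x0 = 0.43,
  k = 3.4) and OA vs. normalized Unc13A (A = 0.05, x0 = 0.37, k = 7.2);
  the PdBU preset uses A = 0.06 with the Unc13A midpoint/slope, chosen so
  the simulated PdBU quantal-density boost (~60%) matches the wild-type
  observation.
- `gate` — receptor gating: OA acts through the Gq-coupled OAMB receptor,
  enriched in Ib terminals (gate 1) and essentially absent from Is
  terminals (gate 0); PdBU, a membrane-permeable DAG mimic, bypasses the
  receptor (gate 1 for both types). OAMB knockdown forces the OA gate to 0;
  the DAG-binding-dead Unc13A(H1723K) rescue forces the gate to 0 for both
  drugs.
- `s` — the fraction of DAG-modifiable Unc13A protein present: 0.2 after
  Unc13A RNAi, 1.4 after Unc13B RNAi (compensatory Unc13A upregulation),
  1 otherwise. The sigmoid alone cannot abolish potentiation after
  knockdown — its low-x tail is ~0.003–0.004, which against an equally
  shrunken basal P_r would *increase* the relative boost — whereas release
  potentiation requires the protein being modified, so the achievable
  amplitude scales with the protein that remains. With this term the
  simulated knockdown reproduces the observed sign structure (no
  significant boost after Unc13A RNAi, an enhanced boost after Unc13B
  RNAi).
- `h` — per-AZ multiplicative lognormal heterogeneity (σ = 0.5, median 1):
  neighboring synapses with identical basal P_r are observed to potentiate
  very differently.
- `ε` — additive zero-mean Gaussian scatter (σ = 0.015) so a minority of
  AZs show decreased P_r, as observed (~23% under OA). Its magnitude is a
  configuration choice, not a claim.

Normalization of `x` uses the wild-type-equivalent maximum, fixed before
any knockdown scaling, so genotype manipulations shift the normalized axis
rather than being normalized away.

Release is Bernoulli per AZ per stimulus — 100 stimuli at 0.2 Hz per epoch
by default — using `basal_pr` before and `modulated_pr` after drug.

### Functional movies

Each released quantum adds a transient with a one-frame rise and
exponential decay (τ = 50 ms) in time, and a 2D Gaussian point-spread
footprint (σ = 140 nm) in space; the drawn peak amplitude (lognormal, mean
0.25 ΔF/F, CV 0.3) is realized exactly at the AZ center. Movie time is
compressed to a fixed window around each stimulus (default 30 frames at
10 ms); at 0.2 Hz the 5 s inter-stimulus intervals carry no signal and
simulating them would only cost disk. Transients are truncated at the trial
boundary. Pixel size (162 nm), frame interval, PSF width and amplitude
statistics are stand-ins chosen so that default events clear the
0.04–0.05 ΔF/F detection band with realistic margin; all are configurable.
Additive Gaussian noise (σ = 0.015 ΔF/F) models photon noise on the
baseline-normalized signal. Raw-counts movies (for testing preprocessing)
multiply a structured resting-fluorescence image by (1 + ΔF/F), apply
monoexponential bleaching, and optionally a rigid integer-pixel drift whose
per-frame shifts are logged as registration truth.

### Structural volumes

Each AZ is painted into Brp and Unc13A channels as a 3D Gaussian blob
(σ = 80 nm xy, 120 nm z — the width of an Airyscan-resolved Brp punctum)
whose integrated intensity equals the AZ's protein weight exactly, on a
50 nm xy / 159 nm z voxel grid (the 11 nm xy pitch of the real acquisition
is configurable but desk-scale volumes use 50 nm). Fixation distortion is a
uniform x/y stretch (0.8–1.3) plus a smooth sinusoidal local warp whose
amplitude must stay below half the AZ spacing; the true transform is
returned for registration-recovery tests.

### Behavior

Larval crawling is a correlated random walk with epoch-dependent speed
under a 5 min acclimation + 15 min dark/light block schedule. Type II
(octopaminergic) firing is a two-state renewal process: tonic Poisson
background (0.1 Hz) plus bursts whose onsets precede each Ib transmission
bout by a 4 s lead; intraburst inter-spike intervals are drawn as
50 ms + exponential, so the 20 Hz intraburst ceiling is never violated. Ib
bouts are boxcar ΔF/F elevations from a renewal process with a refractory
gap.

## Detection

Raw movies are registered frame-by-frame against the first trial's baseline
mean by windowed cross-correlation (integer-pixel by default), bleaching is
removed by a per-pixel log-linear fit to stimulus-free frames, and ΔF/F
uses a per-trial F0 (mean of the pre-stimulus window). The temporal
response template is the average stimulus-aligned profile of
supra-threshold responses, unit peak; provisional pixels are selected with
a matched filter against the canonical kernel (one-frame rise, exponential
decay) because a raw window maximum would select pure noise excursions.
With no supra-threshold response anywhere, the canonical kernel itself is
used, with a warning.

Per trial, the template amplitude is fitted per pixel by least squares over
the response window; a pixel passes if the fitted amplitude is at least the
absolute threshold (default 0.045 ΔF/F, the midpoint of the 0.04–0.05
operating band) *and* at least 1.75× that pixel's quiescent SD (robust,
1.4826×MAD over stimulus-free frames; midpoint of the 1.5–2 band). Passing
pixels merge into events by 8-adjacency gated on trace correlation
(Pearson r ≥ 0.6 over the response window; no printed cutoff exists, so
this is a configurable design value). When one connected group holds
several supra-threshold local maxima of the fitted-amplitude image —
simultaneous release at neighboring AZs bridging into one footprint — the
group is split by nearest maximum and the events flagged `split`; without
this the per-AZ recovery the pipeline is designed for degrades at realistic
AZ spacing. Multiple quanta at one AZ in one trial still merge into a
single event (amplitudes sum), a deliberate undercount at high P_r since
events, not quanta, are counted.

## Localization and synapse ROIs

Each event's spatial profile in its peak frame is fitted with a 2D
elliptical Gaussian plus constant offset on a 7×7 px window (moment
initialization; bounded Levenberg–Marquardt). The window size balances
neighbor-event contamination against fit stability at 162 nm pixels. A
failed or out-of-window fit falls back to the intensity-weighted centroid
and flags the coordinate; events are never dropped. Localization precision
is a rough PSF-width-over-SNR estimate, recorded per coordinate.

Coordinates accumulate into a density map: a 2D histogram on a 4× upsampled
grid smoothed with a 40 nm Gaussian kernel, padded so the integral equals
the coordinate count exactly. Synapse ROIs are greedy density maxima with a
350 nm exclusion radius: take the global maximum, claim coordinates within
350 nm (claimed coordinates stop contributing to the residual density —
otherwise the unclaimed tail of an already-claimed cluster spawns spurious
ROIs just outside the exclusion zone), suppress further peaks within
350 nm, and stop when the residual peak falls below the density two
coordinates would produce (with a 0.75 safety factor for sub-grid kernel
splitting). Each coordinate is assigned to its nearest claiming center,
ties toward the lower ROI id.

## AZ segmentation

AZ candidates are local maxima of the lightly smoothed Brp channel
(anisotropic physical smoothing, σ = 30 nm) above a floor of
max(median + 5×MAD, 0.1% of the peak) — a background-noise estimate rather
than Otsu's threshold, which on a dark-background volume sits above dim AZ
peaks — filtered so surviving maxima are pairwise ≥ 150 nm apart in
physical (anisotropic) distance, ties toward the smaller (z, row, col).
Watershed territories resolve contested voxels. The reported voxel mask is
the half-max core 26-connected to the maximum; protein intensities,
however, are summed over the AZ's territory down to 1% of its peak, always
on pre-smoothing voxel values — a half-max core alone truncates roughly
half of a Gaussian punctum's integrated intensity, and the per-AZ amount,
not the core brightness, is the quantity of interest. Records whose core
collapses below 2 voxels are flagged low-quality; flagged records stand in
for the manual curation step of the original workflow. Normalization is
per NMJ (per motor-neuron type when labels are available) by the group
maximum, putting protein axes on [0, 1]; mean normalization is available
behind a flag since the published axes do not state their scheme.

## Structure–function registration

The global fixation stretch is estimated by grid search over (sx, sy) with
centroid-matched translation, scored by summed nearest-neighbor distance,
then refined by Nelder–Mead over all four parameters; degenerate inputs
(< 3 points, collinear) fall back to translation-only with a warning.

Site matching is anchors-then-consistency: mutual nearest neighbors within
300 nm whose second candidate is ≥ 1.5× farther are accepted as
unambiguous anchors; remaining AZs are processed in order of decreasing
clarity and paired with their nearest free ROI only if the pair's
displacement deviates from the median displacement of the 3 nearest
accepted pairs by less than 150 nm (the gate that operationalizes
"minimize local alignment variance"); accepted pairs join the anchor pool
and passes repeat until no growth. Leftover AZs are reported as candidate
silent synapses. Matching is one-to-one and order-invariant by
deterministic sort keys.

The overlay transform is a 2D locally weighted mean: each control pair
carries an affine fitted to its 8–14 nearest pairs, offset-corrected to
pass exactly through its own target; a query point maps to the
inverse-square-distance-weighted mean of these local affine predictions
(continuous everywhere, exact at control points). With fewer than 8 pairs a
single global affine is used, with a warning. This transform is for
overlay only — all quantification runs on untranslated functional
coordinates. Event-to-AZ assignment is nearest ROI center with unlimited
radius (distance recorded for stricter downstream filtering); ties go to
the lower AZ id; coordinates nearest an unmatched ROI keep a roi-only
assignment.

## Statistics

P_r = events/#stimuli per AZ per epoch, exact counting with silent matched
AZs kept at zero. Quantal density = events per stimulus per µm² of the
functional footprint (the detection-mask area; the original area
measurement is not defined anywhere, so the mask footprint is this
package's definition). Response classification calls an AZ increased /
decreased / unchanged by the sign of ΔP_r, with "unchanged" meaning exactly
zero — counts are integers, so exact ties are meaningful.

Modulation curves are summarized in equal-count bins (default 6) over the
normalized protein axis, mean ± SEM on both axes, bins under 3 AZs merged
into neighbors. The sigmoid y = A/(1+exp(−(x−x0)k)) is fitted by
multistart nonlinear least squares: ≥ 32 starts drawn from data-driven
ranges (A ∈ [0, 2·max|y|], x0 across the observed x range, k ∈ [0.1, 50])
plus deterministic corner starts, best SSE wins, SSE reported on the fitted
points. The fit parameters are *bounded* to those same ranges: an
amplitude beyond 2·max|y| or a midpoint outside the observed x range is not
identifiable from the data, and unbounded fits of shallow curves on few
noisy bins drift into runaway boundary solutions. Fits default to binned
means (matching the figures); raw-AZ fits are available. Amplitude
recovery of a *shallow, non-saturating* sigmoid from 6 noisy bins is
right-skewed even so (best-SSE selection favors slightly ramp-like
solutions); the acceptance checks measure this estimator as-is.

A saturating-exponential alternative y = a(1 − exp(−x/λ)) + c sits behind
the `saturating_exp` model tag. The published formula it corresponds to is
typographically garbled in the source material
(`y=(0.21∗(1+e-x-2.2∗10-7) + 0.01)` — sign and grouping of the exponent
ambiguous); this implementation does not pretend to resolve it and the
model is excluded from acceptance checks.

Hypothesis tests (paired t, Wilcoxon signed-rank, two-sample KS, one-way
ANOVA) wrap scipy with the field's star convention (* < 0.05, ** < 0.01,
*** < 0.001, n.s.). The two-sample KS test is discrete and conservative in
small samples (~2.6% empirical type-I at n = 50 per sample); its
calibration is asserted at n = 500 where it attains the nominal level.

## Behavior analysis

Centroid tracks apply the merge rule: maximal runs of detections whose
consecutive gaps are ≤ 2 s and whose pairwise spread stays strictly under
1 mm collapse to their center of mass at the central frame — the
transitive reading, under which a stationary jittering larva's path length
collapses to near zero while a 1 mm/s run is untouched. Epoch displacement
is cumulative path length over valid steps (matching the tens-of-cm
magnitudes reported for 30 min sessions, which exceed any net displacement
in a 35 mm dish); the acclimation block is excluded from summaries, and an
epoch with no valid samples is reported missing, never zero. Bouts are
maximal intervals above median + 3×MAD lasting ≥ 0.5 s, gaps < 0.5 s
fused. Coupling compares type II firing (events per 50 ms bin) in the 8 s
before each Ib bout against the whole 600 s recording, Wilcoxon
signed-rank across recordings; windows truncated by the recording start
are flagged.

## Pipeline and reproducibility

`run_pipeline` executes simulate → detect → localize → segment → match →
quantify for n simulated NMJs under one scenario. All randomness descends
from a single root seed through named substreams (NMJ index × stage), so
runs are bit-for-bit reproducible from the manifest (config, scenario,
seed, config hash) and stages can be re-run independently. ROIs are built
from the pooled pre+post coordinates so both epochs count against one
synapse set. Motor-neuron-type labels for segmented AZs come from the
simulation's ground truth by nearest-neighbor lookup — the stand-in for
the anatomical labeling an experimenter does by eye. Empty intermediate
results (a movie with no events) degrade to explicitly missing report
sections, never a crash.

## What the simulations do and do not show

The generator reproduces the statistical structure the analysis relies on:
Bernoulli counting statistics, two-decade P_r heterogeneity, sigmoidal
protein-dependence of modulation with receptor gating, PSF-limited imaging
with additive noise, fixation stretch and warp, and burst/bout timing.
It does not model vesicle pools or calcium dynamics, short-term plasticity,
non-Gaussian detector noise, sample-dependent staining variability, tile
stitching, or multi-animal tracking. Passing tests therefore demonstrate
that the algorithms recover what they are designed to recover under the
stated noise model, not that real recordings satisfy that model.

## Problem sizes

Default study conditions are 100 stimuli per epoch and NMJs of roughly
30–50 AZs (6 NMJs per scenario contrast, as in the experiments emulated).
Test fixtures and the pipeline smoke tests use 15–30 stimuli, 2–3 boutons
and 64–96 px fields; the modulation-recovery experiments use 600 AZs × 100
stimuli × 20 seeds. These sizes are the package's defaults for desk-scale
reproduction; every one of them is a config parameter.
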