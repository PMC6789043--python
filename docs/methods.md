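# Methods

This note records the models behind each analysis stage, the synthetic-data
generators used to validate them, and the design choices made where the
underlying assay conventions leave room.

## Calcium transients

**Model.** A transient is described by a baseline F0, peak F, time to peak
T_peak, recovery times T50R/T90R (peak to 50%/90% recovery of F − F0), the
matched rates (R_peak = (F−F0)/T_peak, R50R = 0.5(F−F0)/T50R, R90R =
0.9(F−F0)/T90R) and a relaxation constant τ from a least-squares fit of
`A·exp(−t/τ) + C` restricted to samples between the 10% and 90% recovery
crossings. The offset C is left free; initialisation is τ₀ = T50/ln 2,
A₀ = F − F0, C₀ = F0. Reported per video as the average over detected beats
(at least four expected; fewer warns).

**Trace extraction.** The cell boundary is a global Otsu threshold on the
temporal-maximum projection, keeping the largest connected component after
morphological closing (radius 2 px). Background is the per-frame median of
pixels outside the mask dilated by 5 px, subtracted frame by frame. These
choices are deliberate defaults for a single bright cell on a dark
background; stacks with multiple cells or structured background need a
different segmenter.

**Conventions chosen where none is standard.** Upstroke onset = last sample
below F0 + 5% of (F − F0) before the peak (robust to baseline noise);
F0 = mean of the 100 ms preceding onset. The recovery-crossing search for a
beat extends to the next peak, not to the midpoint of the beat interval,
because T90R can exceed half the pacing period at slow relaxation.

**Generator.** In-cell intensity is `background + F0 + (F−F0)·w(t)` on a
centred disc; background pixels sit at a constant level, so the
background-corrected in-cell mean is exactly `F0 + (F−F0)·w(t)`. The unit
waveform w rises linearly over T_peak (default 0.2 s), relaxes along a
*shifted* exponential `(exp(−s/τ) − c)/(1 − c)` with `c = exp(−T_rel/τ)`,
and then holds at baseline for a diastolic interval (default 0.3 s). The
shifted form is still `A·exp(−s/τ) + C`, so the free-offset fit recovers τ
exactly, while the waveform reaches baseline exactly before the next
upstroke — a truncated pure exponential at 0.5 Hz pacing with τ ≈ 0.6–0.8 s
would leave a ~6–9% residual that contaminates F0 and biases the measured
fold beyond the 1% recovery budget. Ground-truth T50R/T90R are the analytic
crossings of the shifted waveform. Default imaging rate is 50 fps, safely
above the 20 fps floor below which T50R is under-resolved (construction
warns). Intensities are floating point; no camera bit depth or photophysics
(bleaching, motion, indicator saturation) is modelled, so passing tests
demonstrate correctness of the metric definitions, not robustness to those
artefacts.

## Action potentials and optical waves

APD50/APD90 are measured from the upstroke (maximum dV/dt, using forward
differences so a step upstroke localises to one sample) to the first
downward crossing of peak − x%·(peak − resting), with linear sub-sample
interpolation. Repolarization percentages are relative to (peak − resting),
not (peak − 0 mV). Resting potential comes from the most-negative decile of
a gap-free recording when supplied, else the pre-upstroke mean. Traces are
assumed tip-potential corrected upstream. The repolarization τ reuses the
calcium fit machinery on the 10–90% window.

Optical waves: per wave, baseline is the mean of the flanking troughs,
amplitude = peak − baseline, WD50/WD90 are widths at the 50%/90%
repolarization levels between the upstroke and repolarization crossings, and
the maximum depolarization rate is the largest finite-difference slope on
the upstroke; per-wave values are averaged.

The stylized generator AP is a single-sample upstroke followed by an
exponential repolarization with τ = APD90/ln 10, which places the 90%
crossing exactly APD90 after the upstroke (and APD50 at ln 2/ln 10 ≈ 0.30
APD90 — a repolarization shape without a plateau, adequate for validating
crossing detection, not for modelling AP morphology). Sampling is 10 kHz.
Waves are symmetric triangles: base width W gives WD50 = W/2, WD90 = 0.9 W
in closed form.

## Beat-rate variability

The beat-interval series BI_n yields ΔBI_n = |BI_{n+1} − BI_n|, the fraction
of ΔBI strictly above 250 ms, and a Poincaré ellipse on the lag-1 pairs
(BI_n, BI_{n+1}): centred on the componentwise mean, axes along the
eigenvectors of the sample covariance, half-lengths `sqrt(χ²₀.₉₅(2)·λ)`.
This covariance-chi-square construction is the single biggest interpretive
choice in the package — "a fitted 95% ellipse" admits several definitions —
and the generator and analyser deliberately share it, so recovery tests
validate internal consistency plus the population identity below, not a
particular published ellipse convention. Beat detection uses an adaptive
prominence threshold (30% of the dynamic range) with a 0.25 s refractory
period.

The generator draws stationary Gaussian AR(1) intervals whose lag-1
correlation ρ is set from the target axis ratio r via the population
identity `r = sqrt((1+ρ)/(1−ρ))` (r = 4.36 ⇒ ρ ≈ 0.900). Defaults: mean
interval 1.5 s, marginal SD 0.1 s — a slow, spontaneously beating mutant
phenotype with physiologically positive intervals. Note that at ρ ≈ 0.9 the
process has long memory, so the *sample* axis ratio of a single 500-interval
series has ≈ 10% sampling spread; recovery checks and the acceptance script
therefore average the ratio over independent seeded replicates and document
the per-draw spread rather than relying on one draw.

## Micropost twitch mechanics

Deflections are Euclidean distances from per-post rest positions; total
force is `Σ k_post·Δ_i` with k_post = 56.5 nN/μm and 6 μm spacing. Twitch
force is the force-trace peak minus its diastolic baseline (mean of the
lowest-decile frames); the absolute peak is also reported since published
values do not always state which convention is used. Twitch velocity is the
peak interval slope of the total deflection during contraction. **Power is
not given a standard definition on this platform**: the package reports
instantaneous mechanical power — total force × total deflection velocity —
at its contraction-phase peak, which is dimensionally consistent with the
fW values reported for such assays (1 nN·μm/s = 1 fW). Power pairs each
interval slope with the trapezoidal mean force over the same interval,
making the discrete estimate second-order accurate away from slope breaks.

When rest positions are missing they are estimated from the diastolic
extreme of each post's trajectory: project onto the principal axis, pick the
denser extreme (posts dwell longest at diastole), and average the 10%
closest frames. Image-based post tracking is out of scope; inputs are
centroid time series.

The generator reuses the calcium waveform shape for deflections, splits the
peak total deflection F/k unevenly across posts deflecting toward the grid
centroid, and, when a power target is given, solves the linear-rise time
from `t_rise = F²/(k·P)` (snapped to the 250 fps frame grid, chosen so the
mid-interval power estimate sits within the 1% recovery budget).

## Mitochondrial flux

Segment summaries default to the within-segment mean (noise-robust; the
vendor's "last rate before injection" is available via `summary="last"`;
the two agree exactly on plateau data). With summaries b (basal), o
(oligomycin), f (FCCP), a (antimycin/rotenone): max OCR = f − o,
ATP production = b − o, proton leak = o − a, non-mitochondrial = a, so
ATP + leak + non-mito = b holds as an exact identity on any input.
Palmitate utilization = mean OCR over the second palmitate segment minus
the last value of the first. OCR is divided by per-well cell counts before
metrics. The generator chooses plateau levels so the metric formulas return
the preset targets exactly (non-mitochondrial OCR defaults to
10 pmol/min/cell, a value the printed metrics do not constrain); with
additive noise of SD σ and m points per segment, difference metrics have
SD ≈ σ·sqrt(2/m), which the tests verify by Monte-Carlo.

## Enrichment and scRNA-seq QC

DE sets use mean normalized expression with pseudocount 1: up = fold > 1.5,
down = fold < 1/1.5, both strict; genes whose total expression over the
compared samples is ≤ 1 are excluded. (A full negative-binomial DE fit is
deliberately not reimplemented — the net-benefit score consumes only the
±1.5-fold sets.) Enrichment is the upper-tail hypergeometric probability
P(X ≥ overlap), uncorrected for multiple testing, matching the score's
construction; the net benefit is `log10(p_down) − log10(p_up)`, positive
when maturation pathways are preferentially upregulated, and antisymmetric
under exchanging the up/down sets. The QC filter keeps a cell iff mito
fraction ≤ 0.40 and detected genes ≥ 200 and total UMIs ≥ 2000 — the
thresholds are phrased as strict violations, so equality passes. Cluster
heat-map values are per-gene z-scores across all cells averaged within
cluster; zero-variance genes are flagged and zeroed rather than propagating
NaN.

## Morphometrics

Area is pixel count × pixel_size²; circularity is 4πA/P², clipped to 1.
The perimeter P uses the subpixel marching-squares boundary smoothed with a
5-point circular moving average: the raw pixel boundary over-measures smooth
outlines (a rasterized r = 50 disc comes out ~5% long, biasing circularity
to 0.91), while the smoothing restores the disc to 0.994 and leaves a
100 px square at 0.80 (ideal π/4 ≈ 0.785). Manders coefficients default to
the classic zero threshold (any positive signal counts, so identical
channels give M1 = M2 = 1); per-channel Otsu thresholds are available via
`thresholds="otsu"` for images with non-zero background. The nucleation
test is the Pearson chi-square on the 2×4 table of 1/2/3/≥4-nucleated cell
counts (df = 3), with an optional collapse of categories empty in both
groups.

## Lipidomics

The name grammar covers `CL(a:b/c:d/e:f/g:h)`, the `[a:b][c:d][e:f][g:h]`
bracket shorthand, `tetra[a:b]-CL`, `MLCL(...)` (3 chains), `TG(...)`
(3 chains), and `AC`/`FFA` single chains with an optional `-OH`
hydroxylation suffix; chain counts are enforced at parse time and the
canonical renderer round-trips through the parser. mTIC normalization
scales each sample so its identified-species sum equals the cross-sample
mean of those sums (unknown features scale along). Because that target is
itself data-derived, rescaling one sample's raw values changes all
normalized values by one common global factor while leaving every sample's
normalized *profile* unchanged — the invariance that matters for fold
changes and class ratios. "Long-chain" means ≥ 14 carbons on a chain and
"medium-chain" 6–12 (configurable); class summaries are per-sample sums
over predicate-selected species, and fold-change matrices divide by the
reference-group mean (zero-reference species are flagged, reference columns
average to 1). The ≥ 50%-per-group presence filter is provided as a table
operation; upstream MS feature deconvolution is out of scope. Fold changes
on real MS data are not recovery targets; the operations are validated on
synthetic tables with construction-time bookkeeping sums.

## Synthetic-data scope

The generators emulate the *structure* each analysis consumes — waveform
shapes, plateau segments, planted fold changes and QC violations, parseable
species names — with known ground truth, under additive Gaussian noise
only. They do not model photophysics, motion, well drift, sequencing depth
effects or MS matrix effects, so green tests certify the estimators against
their definitions and oracles, not robustness to real-world artefacts.
Problem sizes throughout (5-beat stacks at 50 fps, 10 kHz APs, 500-interval
rhythm series, 6-well plates, hundreds of genes/cells) were chosen as the
smallest that exercise every code path at full numerical fidelity.
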