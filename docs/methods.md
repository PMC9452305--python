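# Methods

`viscmap` implements the analysis chain of a volumetric two-photon
calcium-imaging experiment probing visceral sensory representations in the
brainstem, together with a synthetic experiment generator that provides
ground truth for every stage. This note describes the models, the parameters
that matter, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Imaging model and the synthetic generator

One experiment (one field of view, FOV) covers 509.12 × 509.12 × 320 µm
imaged as 5 planes of 512 × 512 pixels at 1.25 volumes/s, containing
`n_neurons` (default 2,800; the test-scale default study uses 2,000)
nuclear-labelled neurons. Each neuron is either a non-responder or a
responder tuned to one or more organs:

- `frac_responsive` (default **0.40**) — fraction of neurons responding to
  at least one organ. Not reported quantitatively for the real preparation;
  chosen once as a realistic mid-range value for anaesthetized brainstem
  recordings.
- `frac_selective` / `frac_multi` (**0.90 / 0.10** of responders) — single-
  vs multi-organ tuning, matching the reported ~90% single-organ selectivity.
- `frac_rapid` (**0.56**) — rapidly adapting fraction, matching the reported
  rapid/slow cluster sizes (696 vs 548).
- Organ domains — responders are placed as an isotropic in-plane Gaussian
  around their dominant organ's domain centroid (`spread_um` = **25 µm**);
  the stomach and duodenum centroids sit **60 µm** apart, the reported
  centroid segregation scale. Depth is uniform. Non-responders are uniform
  in the FOV.
- Response amplitudes — lognormal across neurons (median **0.6** ΔF/F,
  log-SD **0.35**); not reported in the source material, chosen once as a
  realistic nuclear-indicator amplitude scale. Multi-organ neurons draw their
  secondary-organ amplitude as Uniform(0.4, 0.9) of the dominant one, so one
  organ always dominates.
- Dose dependence — a Hill curve in stimulus intensity (exponent **1.5**,
  EC50 defaulting to the organ's median protocol intensity), normalized to
  its value at the organ's strongest protocol intensity so the drawn
  amplitude is the peak-dose ΔF/F.
- Kinetics — slow responders rise with τ = `kernel_rise_s` (**0.3 s**) and
  sustain a plateau for the stimulus, then decay with `kernel_decay_s`
  (**1.5 s**); rapid responders additionally relax during the stimulus with
  `adapt_tau_s` (**10 s**), putting the offset response under 2% of peak for
  a 40-s stimulus. Templates are clipped to exactly zero below 10⁻⁶ of unit
  amplitude, so traces are identically zero outside stimulus-driven
  transients (this matters for exact-tie behaviour below).
- Cross-inhibition — for each configured (suppressed, suppressor) organ pair
  a fraction of suppressed-organ responders (defaults **0.29** for
  duodenum-by-stomach and **0.174** for stomach-by-duodenum, the reported
  fractions) lose `strength` × dose(suppressor) of their amplitude whenever
  the suppressor is presented simultaneously.
- Raw fluorescence — `F_i(t) = B_i (1 + drift(t)) (1 + ΔF/F_i(t)) + B_i ·
  noise_sd · ε(t)` with per-neuron baseline `B_i` ~ Uniform(100, 200) a.u.,
  linear photobleaching `drift_rate` = **2%/min**, and white ΔF/F noise
  `noise_sd` = **0.05**. All draws flow from a single `seed`; a fixed seed
  reproduces the experiment bit-for-bit.

Rendering draws each neuron as a 2-D Gaussian nucleus (σ = 2 px) on its
nearest plane, peak intensity tracking its fluorescence, over a constant
background with additive pixel noise. There is no axial point-spread
function, no brain motion and no vasculature; movies exist to exercise the
detection/extraction path, not to look realistic.

## ROI detection and extraction

The time-averaged image is cross-correlated (normalized) against a Gaussian
kernel sized like an average nucleus; the correlation map is thresholded
(default 0.5) and connected components within an area band (default
20–400 px; tests at reduced magnification use a lower bound of 5 px) become
ROIs, with correlation-weighted centroids mapped to µm. A constant image
yields no detections rather than an error. Fluorescence is the plain mean
over mask pixels per frame. Manual mask curation is deliberately replaced by
the area filter to keep runs reproducible.

## ΔF/F, detrending, thresholds

ΔF/F = (F_t − F0)/F0 with F0 averaged over a 24-s pre-stimulus window.
Detrending fits a line to non-stimulus frames — additionally excluding 10
frames after each stimulus offset so decay tails do not bias the fit — and
removes it **by division** on the 1 + ΔF/F scale: photobleaching is
multiplicative, and subtraction would attenuate late-recording response
amplitudes (which, in paired-series experiments, systematically biases
mix-vs-single comparisons). Duodenal chemical perfusion recordings skip
detrending entirely.

Per-stimulus baseline statistics are computed **on the detrended ΔF/F
trace**: F0 and s0 over the 24-s window (30 frames at 1.25 Hz), the 7-frame
(mechanical) and 25-frame (chemical) local pre-onset windows, and the
response threshold θ = F0 + 2.5 s0. Computing θ on the ΔF/F scale (where
F0 ≈ 0) is the only reading under which "ΔF/F above θ" is dimensionally
coherent.

## Response criteria

Mechanical (window = stimulation period): responsive iff ΔF/F > θ for more
than three continuous frames (read strictly: ≥ 4) **and** above
max(F0′ + 2 s0′, θ) for at least two continuous frames. Chemical (window =
stimulation period plus 20 post-offset frames): more than four continuous
frames (≥ 5) above θ, plus the same 2-frame local-bound condition using the
25-frame window. Response magnitude is the maximum of the 5-frame centered
moving average (window shrinking at trace edges) in the matching window,
minus θ; negative values are preserved in tables and clipped only when
reported as response sizes.

Kinetic classes come from k-means (k = 2, 10 restarts, fixed seed) on
peak-normalized onset-aligned responsive traces; the cluster whose mean
trace carries more of its early activity into the late third of the window
is labelled *slow*. Fewer than two traces cannot be clustered (*none*); a
degenerate single-cluster input is labelled *slow* by convention.

FOV inclusion filters: ≥ 5 responders to every stimulus (glucose-style
experiments), ≥ 2 responders per analysed stimulus (standard), ≥ 2
selectively tuned neurons per stimulus of a pair (spatial pair analyses).

## Tuning and correlation structure

A neuron's organ set contains every organ with ≥ 1 positively called
stimulus; selectivity is *selective* (1 organ), *multi_organ* (≥ 2) or
*none*. The dominant organ is the argmax-magnitude responsive organ, ties
broken by configured organ order (logged). Stimulus-pair Pearson
correlations run over all neurons responsive to ≥ 1 stimulus of the analysed
set, using raw (possibly non-positive) magnitudes for non-called stimuli;
zero-variance columns are reported missing. Responder-set convergence for a
stimulus pair reports |A∩B|/|A|, |A∩B|/|B| and the relative likelihood
P(B|A)/P(B).

## Segregation index

For groups X (n points) and Y (m points) in one image plane:

    SI = numerator / denominator
    numerator   = (1/(n+m)) Σ_points [mean distance to other group
                                      − mean distance to own group (self excluded)]
    denominator = mean over label permutations of (1/(2(n+m)))
                  Σ_points [mean cross distance + mean within distance]

with 1,000 uniform random permutations by default (drawn with replacement
across draws, fixed seed). When (n+m)! ≤ 10,000 all permutations are
enumerated and the result is exact. The denominator's within-group sum is
indexed symmetrically for both groups (the mirror of the X-group term); the
implementation is vectorized over permutations and verified to ≥ 10
significant digits against a literal nested-loop transcription with shared
permutation draws. SI requires ≥ 2 points per group, is symmetric in the
groups, and is invariant under translation, rotation and uniform scaling.
Pooling FOVs divides the mean of per-FOV numerators by the mean of per-FOV
denominators. SI is computed on in-plane (x, y) coordinates; pass 3-D
coordinates explicitly for depth analyses.

Distance-shuffle comparisons reassign labels within each FOV preserving the
observed per-FOV label frequencies, controlling for regional density
variation; the same contract serves neuron-vs-bouton structure comparisons.
The enrichment index is (P⁺ − P⁻)/(P⁺ + P⁻) over Cre-positive vs
Cre-negative response frequencies, undefined (None) when both are zero.
Density maps are plain Gaussian-kernel rasters normalized to integrate to 1
per label. Bouton centroids come from Canny edges, hole filling and an area
filter.

## Paired-stimulus suppression

In the series S1, D1, M1, S2, D2, M2 (64-s gaps so responses decay fully
before the next baseline window), a neuron *selectively* responsive to the
target organ (responsive to both its single trials, to neither of the paired
organ's) is suppressed iff d_M1 < d_1, d_M2 < d_2 and (d_M1 + d_M2)/2 < d_2,
all strict, where d_2 is the **second** single trial — implemented literally
as printed, including the asymmetric criterion (3). Ties are not suppressed.

Two properties worth knowing:

- On noiseless, drift-free synthetic data (analysed without detrending —
  there is no trend, and a linear fit to transient tails would leave ~10⁻⁵
  residues that break exact ties) the classifier reproduces ground-truth
  suppression flags exactly: non-suppressed neurons produce bitwise-equal
  mix and single magnitudes, which the strict inequalities reject.
- Under measurement noise the strict inequalities have a substantial chance
  level: for a non-suppressed neuron each mix-vs-single comparison is a coin
  flip regardless of SNR, so roughly a quarter of non-suppressed neurons are
  over-called. This is intrinsic to the criteria, not to this
  implementation; recovered fractions on noisy data therefore sit well above
  the configured ground truth, and exact-recovery claims are made only on
  noiseless series.

## Test and benchmark scales

The default benchmark study uses 2,000 neurons, one 760-frame multi-organ
protocol (graded stomach and duodenum stretches plus laryngeal water), the
paired series at 2,000 neurons, and a rendered round-trip at 60 neurons on
two 256 × 256 planes — sizes chosen so the full suite and the acceptance
script each run in well under a minute on one CPU while keeping binomial
CIs tight enough to be meaningful. Stochastic checks are seeded; calibration
checks on single draws use 95% CIs, and the generator's tuning-draw
convergence check uses an exact binomial test at the 0.1% level over ten
pooled draws so that ordinary sampling extremes at fixed seeds do not mask
logic regressions.

## What passing tests do and do not show

The synthetic benchmark validates the machinery: criteria boundaries,
statistic definitions (against independent oracles), parameter recovery at
realistic SNR, and end-to-end consistency of rendering, detection,
extraction and calling. It does not validate performance on real data —
brain motion, neuropil contamination, overlapping nuclei, non-Gaussian
noise, anaesthesia-state drift and manual curation are all absent from the
generator — and recovered fractions (selectivity, suppression) depend on the
assumed amplitude distribution, for which no published values exist.
Weak near-threshold secondary responses of multi-tuned neurons are
occasionally missed, which biases recovered selective fractions upward by
roughly one percentage point at the default SNR.
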