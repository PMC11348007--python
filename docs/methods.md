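# Methods

This note documents the models, algorithms and numerical choices behind
the package, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Spectral model and parameterization

Inside the fit band (default 3–35 Hz) the log10 power spectrum is modelled
as an aperiodic line plus Gaussian peaks:

    model(f) = b − x·log10 f + Σₙ aₙ·exp(−(f − μₙ)²/(2σₙ²))

Only the "fixed" aperiodic mode (no knee) is implemented; the band is
narrow enough that a knee term is not identifiable and the analysis this
package supports concerns the exponent, not the knee frequency.

The fitting procedure follows the canonical iterative decomposition used
throughout the aperiodic-EEG literature:

1. **Initial aperiodic fit.** The model is linear in (b, x) in log-log
   space, so the initial fit is the closed-form least-squares line (no
   iterative seeding is needed; any seed converges to the same solution).
2. **Robust refit.** Residuals above the initial line are clipped at zero
   and thresholded at the 2.5th percentile of the clipped distribution;
   only bins at or below the threshold (i.e. on or under the line) are
   refit.  Because oscillatory peaks only add power, this pulls the line
   to the spectrum's lower envelope and removes the upward exponent bias a
   mid-band peak induces.  A floating-point tolerance (1e−12) keeps exact
   noise-free lines intact.  With roughly half the clipped residuals at
   zero, any small percentile gives the same threshold of 0; the value is
   exposed in `FitSettings.robust_percentile`.
3. **Iterative peak extraction** from the flattened spectrum: take the
   largest residual; stop when it falls below
   max(`min_peak_height`, `peak_threshold` × SD(residual)); seed a
   Gaussian there with a half-height-width heuristic (clipped to
   `peak_width_limits`/2); subtract; repeat up to `max_n_peaks`.  Guesses
   hugging a band edge (within one bandwidth) or overlapping a larger
   peak (centers closer than 0.75 bandwidths) are dropped, then all
   retained Gaussians are refined jointly by bounded least squares
   (analytic Jacobian; amplitude ≥ 0, center within the band, σ within
   the width limits; ties at equal residual maxima resolve to the lowest
   frequency via argmax, so fits are deterministic).
4. **Final aperiodic fit** on the peak-removed spectrum, followed by **one
   joint bounded least-squares refinement of all parameters together**
   (aperiodic + peaks, peak count fixed).  The staged procedure leaves a
   small coupling between the line and the Gaussian tails; the joint
   refinement removes it and recovers noise-free spectra essentially
   exactly (errors ~1e−12), which the staged procedure alone does not.

Goodness of fit is R² = squared Pearson correlation between observed and
modelled log10 power on the fit grid (33 bins at the default 1-Hz
resolution), plus the mean absolute error in log10-power units.  Spectra
with ≤ 3 in-band bins refuse peak fitting and return an aperiodic-only fit
with a warning flag — an 8-peak model is meaningless there.

**Default settings** (`FitSettings`): band 3–35 Hz; peak full-width limits
[2, 8] Hz (σ ∈ [1, 4]); max 8 peaks; `min_peak_height` 0.05 log10-power;
`peak_threshold` 2.0 SD; overlap guard 0.75 bandwidths; edge guard 1
bandwidth.  These are the standard toolbox defaults for this analysis and
are exposed rather than hard-coded.

**Spurious peaks under bin noise.** With i.i.d. log-power noise of SD 0.05
per bin — the ensemble used for validation — the default stopping rule
*will* pick up noise excursions: the maximum of 33 independent N(0, 0.05)
bins exceeds the 2-SD threshold in roughly half of peak-free spectra, so
small spurious peaks (amplitudes ~0.1) are common by construction, exactly
as with the canonical algorithm on real noisy spectra.  This does not
degrade the exponent: the joint refinement decouples the line from the
small extra Gaussian, and the median absolute exponent error over the
validation grid stays ≤ 0.05.  Tests assert zero fabrication on
noise-free spectra and accuracy (not peak count) on noisy ones.

## Welch spectral estimation

PSDs use 0.25-s Hamming-tapered segments with 50 % overlap.  At 256 Hz the
native 64-sample segment yields 4-Hz resolution — about 8 bins in the fit
band, which under-determines a multi-peak model — so segments are
zero-padded to `n_fft = max(256, nperseg)` (the common default of standard
Welch implementations), giving a 1-Hz grid and 33 in-band bins.  Segments
are mean-detrended before tapering to keep DC leakage out of the 3-Hz bin.
Both choices are config-exposed (`WelchSettings`).

Per analysis cell (participant × electrode × prime × flanker × period) the
segments of all correct trials are pooled and averaged into a single
spectrum; with equal-length trials this is exactly the mean of per-trial
Welch spectra (tested against scipy's estimator as the independent route).
Cells with zero correct trials become explicit `MissingCell` markers which
propagate as NaN rows of the exponent table; they are never silently
averaged over, and the ANOVA refuses incomplete designs by listing the
offending cells.

## Synthetic data generator

The generator emulates the study design: 25 participants × 2 sessions
(placebo / MPH) × 384 trials in 4 blocks, the four prime × flanker
congruency conditions equally frequent and shuffled within block, RSI
jitter 1000–1200 ms, event timing fixation 100 / prime 30 / mask 30 /
target 100 ms with a 2000-ms response window, 60 electrodes at 256 Hz, and
two 1000-ms analysis windows per trial.  Correctness is Bernoulli per
condition (default accuracy 1.0 so the correct-only filter is exercised
without shrinking cells).

The exponent ground truth per cell is

    x = base (3.40) + subject effect (SD 0.20)
        + 0.129·[MPH] + 0.124·[within-trial]
        + (0.026·[prime-incongruent] + 0.020·[flanker-incongruent])·[within-trial]

optionally scaled per electrode by a spatial map for planting localized
effects.  The drug and period defaults match the brain-wide condition-mean
contrasts reported for this task design in the pharmaco-EEG literature; the
prime and flanker defaults are plausible small values (no electrode-level
ground truth exists for them) and are configuration, not constants.  Condition effects apply to the within-trial window only:
pre-trial activity precedes the stimulus and cannot carry congruency
information.  Pre-trial windows are generated as stationary background;
first trials of a block are not treated specially.

**Time-domain route.** Epochs are spectrally shaped Gaussian noise:
independent complex bins with amplitude set from the target power law,
inverse-transformed per trial (exact control of the process spectrum, no
filter-design artifacts).  Two estimator-side biases would otherwise
distort the *measured* slope: segment windowing smears steep spectra
(out-of-band low-frequency power leaks into the 3–6 Hz bins), and
per-segment detrending depresses the lowest bins.  The generator therefore
calibrates itself against the estimator: the expected pooled Welch
spectrum is a linear map `E P = K q` of the per-bin generation power `q`,
`K` is computed once by pushing unit basis bins through the exact segment
pipeline, and the generating slope/offset are adjusted by a short
fixed-point iteration until the *expected measured* log-log slope over
3–35 Hz equals the requested exponent (residual bias ≤ 0.02 across
x ∈ [0, 3.5]; the generation spectrum is plateaued below the band to stop
leakage dominating the lowest bins).  Exact bin-wise inversion is
impossible for steep spectra — the estimator's resolution floor is real —
so individual band-edge bins retain the same distortion real recordings
have; only slope and offset are calibrated.

Oscillations are added in the time domain as amplitude- and
center-jittered sinusoids per trial, which produces Gaussian-like bumps in
the trial-averaged PSD rather than spectral lines.  The measured bump is
broader than the nominal bandwidth because the Welch kernel (≈ 4-Hz
mainlobe) convolves it — again matching what real data do at these
settings.

**Fast route** (`mode="spectra"`, the default): per-cell power spectra are
drawn directly from the log-spectral model with i.i.d. bin noise
(`noise_sd`, default 0.05, interpreted as the residual noise of a
trial-averaged cell spectrum, held constant across cells).  This route is
exact with respect to the model and is used for large validation
ensembles.

**What the generator does not emulate:** ERP waveforms, artifacts, volume
conduction / spatial correlation between electrodes, non-stationarity
within trials, and any behavioural RT structure.  Passing tests therefore
demonstrate correctness of the estimators and inference under the model's
assumptions — not robustness to real-data pathologies upstream of the
clean-epoch interface.

## Inference

**Within-subject factorial ANOVA.** All factors have two levels, so every
main effect and interaction is a single-df contrast: per subject, the
cells are combined with the ±1 product coding of the participating
factors; F = (mean/SE)² of the contrast scores with df (1, n−1);
partial η² = F/(F + df2).  This is algebraically the squared paired t
(verified to 1e−10 against scipy and against statsmodels' repeated-measures
ANOVA for all 15 effects of the 2⁴ design).  Sphericity corrections are
the identity for 1-df effects, so Greenhouse–Geisser is noted rather than
estimated; ε estimation for >2-level factors is out of scope.  Follow-up
ANOVAs per split level apply Bonferroni correction (p·m, capped at 1).
Zero-variance contrasts are defined as F = 0, p = 1 when the mean is also
zero (identical conditions), F = ∞, p = 0 otherwise.

**Cluster-based permutation test.** Per electrode, the paired statistic is
the one-sample t of the condition differences (or its square, thresholded
as F at sample-level α = .005 with df (1, n−1); the t variant thresholds
two-sided at α = .05 — no standard t threshold exists for this use, so it
is config).
Suprathreshold electrodes are grouped into connected clusters on the
montage adjacency (separately by sign for t); the cluster mass is the sum
of member statistics; the null distribution of the *maximum* |mass| is
built from within-subject sign flips of the paired differences — exact
exchangeability under the paired null, max-statistic family-wise error
control.  p = (1 + #{null ≥ observed})/(1 + n_permutations): the observed
labelling counts, so p is never 0, and ties count against significance.
The permutation t maps are computed vectorised (sign matrix × differences;
per-subject sums of squares are flip-invariant), so 1000 permutations cost
one matrix product.

**Adjacency.** The emulated equidistant 60-electrode cap defines no
neighbourhood graph, so the default is synthetic: a sunflower (Fermat
spiral) layout on the unit disk — a deterministic near-equidistant scalp
projection — Delaunay-triangulated, with edges longer than 1.5× the median
pruned.  The result is symmetric, irreflexive and connected; users can
supply an explicit edge list instead (`MontageAdjacency.from_edges`).

## Pipeline, determinism, formats

`RunConfig` is fully serializable; every run writes its config verbatim
into the output directory together with one file per stage (trials,
spectra, fits, exponents, ANOVA, clusters, report).  All randomness derives
from the single run seed through named seed streams, so reruns are
bit-identical.  Tables are TSV; epochs are `.npy` arrays with a JSON
sidecar (sampling rate, window, channel names) and a TSV trial table.

## Validation scale choices

The validation harnesses run at the sizes a desk machine handles while
keeping the study's statistical structure: the fit-quality ensemble uses
1000 spectra; the null-calibration study uses 2000 replicates of the full
25 × 60 paired design with 1000 permutations each; the end-to-end
effect-recovery check uses 20 seeded runs of the fast spectrum route with
25 participants and 8 electrodes (electrode count affects only the
brain-wide averaging, not the within-subject contrast being tested).
Epoch-mode generation at full scale (≈ 5 GB of epochs per run) is
exercised at reduced scale in the unit tests; nothing in the code limits
running it at full scale.

## Known limitations

* No knee-mode aperiodic fits; exponent inference only (no offset
  analyses, no Bayes factors).
* Clusters are over electrodes only — no time- or frequency-dimension
  clustering.
* The ANOVA handles fully within-subject 2-level designs; between-subject
  factors and >2-level factors are out of scope.
* The generator's electrodes are statistically independent; spatial
  smoothness of real scalp fields (which enlarges real clusters) is not
  modelled.
* Preprocessing (filtering, ICA, channel interpolation) is upstream of
  this package: the interface starts at clean epochs.
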