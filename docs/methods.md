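# Methods notes

This note records the models, parameter choices, numerical conventions and
known limitations behind `ppcdrift`. Frame intervals are 0-based and
half-open throughout; the default timing is 30 Hz with 200-frame trials:
sample [0, 120), delay [120, 170), reward [170, 200).

## Signal model and event-related detection

A calcium transient is modeled as an impulse convolved with the
double-exponential indicator kernel c(t) = e^(−t/τ_d) − e^(−t/τ_r). Only
the decay constant is well determined by indicator identity (1.0 s
cytosolic, 3.0 s nuclear); the rise constant defaults to 0.1 s, typical of
fast GCaMP variants, and is configurable. Kernels are peak-normalized so
fitted amplitudes are in ΔF/F units.

Detection regresses each pixel/neuron trace on event-locked templates and
applies a one-sample t-test to the fitted per-event amplitudes,
t = β̄/(s/√k), df = k − 1. The test is one-tailed toward positive
activation by default (calcium events are positive-going); a two-tailed
variant sits behind a flag. Degenerate fits are resolved by contract:
s = 0 with β̄ > 0 is significant with p = 0; s = 0 with β̄ ≤ 0 is not.
Amplitudes below 10⁻⁹ of the largest fitted amplitude are snapped to zero
first — pure float round-off otherwise produces a "perfectly consistent"
tiny positive amplitude and a spurious p = 0 under that contract.

Template construction: each task-event regressor is the binary presence
indicator of the event over its phase window, convolved with the kernel
and normalized to peak 1 — one column per matching (by default correct)
trial. A smoothed indicator, unlike a single onset-anchored kernel copy,
captures responses peaking anywhere within a multi-second phase. Columns
are truncated at their trial's end, consistent with the generator's
trial-independence; an onset-anchored point-event variant is available
(`impulse=True`). No detrending is applied to input traces, and no
multiple-testing correction is applied across pixels (a Benjamini-Hochberg
option exists but is off by default, matching common practice for this
detector). Significant pixels are clustered into ROIs by 8-connectivity
(Moore neighborhood) via `skimage.measure.label`.

Neuron classification fits all six regressor groups ({right, left} ×
{sample, delay, reward}) in one joint design, then tests each group's
amplitude vector separately at `alpha_neuron = 0.01` (pixel-level default
is 0.05). Joint fitting matters: kernel tails overlap adjacent phase
windows, and independent per-group fits would attribute the same variance
twice. A neuron's *phase set* contains every phase with a significant
regressor; because a real transient near a phase boundary deterministically
bleeds into the next window, the set may legitimately contain an adjacent
phase even for a perfectly phase-locked neuron. The *primary phase* — the
significant regressor with the largest mean amplitude — is therefore the
label used for ground-truth comparison, and both are reported. Direction is
left/right if only that direction's regressors pass, "nondirectional" if
both pass; neurons whose per-phase directions disagree are flagged
ambiguous rather than silently relabeled. Directional neurons whose mean
in-phase activity on correct opposite-direction trials strictly exceeds
their preferred-direction mean are excluded (guards against slow baseline
drifts); equality retains the neuron.

## ROC indices and permutation validation

PI, RI and PSI all equal 2·(auROC − 0.5) with right (or in-phase) as the
positive class; ties earn 0.5 credit, making the auROC identical to the
exhaustive pairwise count. The implementation uses the rank-sum identity
with midranks; tests verify it against brute-force pairwise counting and
scikit-learn. RI optionally normalizes pooled frame values by the neuron's
maximum ΔF/F; as a positive rescaling this cannot change the index and is
kept for interface parity only. PSI pools both nonpreferred phases into a
single comparison set. All indices are invariant under strictly increasing
transforms of the inputs — a property test, and the reason no further
normalization choices matter.

Permutation validation computes a per-trial index (preferred-phase mean
minus the mean of the other phases), with the session statistic its trial
average. The session-level null shuffles which phase counts as preferred
independently per trial (1,000 shuffles; Z-score and 95th-percentile
threshold). The per-trial p < 0.05 threshold, by contrast, is built from
non-identity relabelings only: with the identity assignment included, one
third of the null mass equals the true signal itself, the 95th percentile
lands inside the signal cluster, and even a perfectly phase-locked neuron
could never pass more than ~15% of its trials — the intended "passes every
trial" reading would be unattainable by construction.

## Trajectory space, distances, TSI

Direction-selective neurons (all phases) are aligned to a common
preferred-direction frame by flipping left-preferring neurons' trial
labels. Conditions are two-letter codes (stimulus, response; P = preferred,
O = opposite). Because each neuron group draws a condition's trials from
different physical trials, condition averages are assembled per group and
concatenated across neuron columns.

PCA is fitted on Z-scored (per-neuron mean 0, sd 1; σ floor 10⁻¹², flagged)
trial-averaged activity of a random 50% of PP trials; the held-out PP half,
OO, and the error conditions are projected into the top five components.
The covariance is divided by frames − 1 (frames are the samples); the
divisor does not affect eigenvectors or explained-variance fractions.
Loading signs are fixed so each component's largest-magnitude weight is
positive, making fits reproducible. The split is repeated 100 times
(seeded); per-frame Euclidean distances between iteration means give d0
(fit-half vs held-half of PP), d1 (PP↔OO), same-stimulation (PP↔PO) and
same-response (OO↔PO) series, with per-iteration values retained for the
distance ROC. Error trials never enter the fit — asserted by a test that
zeroes all error-trial frames and recovers identical loadings.

TSI = (dOO − dPP)/(dOO + dPP), in [−1, +1], undefined (NaN) only when both
distances vanish; +1 is attained exactly at dPP = 0.

## Coding directions

Modes are window-mean differences of trial-averaged correct activity,
l2-normalized: CD_sample frames [65, 115), CD_delay [120, 170), CD_reward
[170, 200); D_reward contrasts the first reward second [170, 200) with the
last delay second [140, 170), pooled per condition over both correct
directions and then averaged. Gram-Schmidt is applied in the stated orders
(CD_reward, D_reward, then CD_sample or CD_delay); a residual norm below
10⁻⁸ raises rather than returning a near-zero mode. Projections are
normalized by the mean correct-right in-window value (that mean is 1 by
construction; a zero constant falls back to unnormalized output with a
warning). Residual separation is read as
[(mean R_error − mean L_error)] / [(mean R_correct − mean L_correct)] of
window-mean projections — the only parenthesization that yields a
deviation-from-correct ratio. The reaction-time check projects each trial
onto CD_delay averaged over the final delay second, takes the signed
distance to the midpoint between mean correct-right and correct-left
projections (positive toward right), and correlates it with RT relative to
the session median.

## LDA-SNR, SVM, correlations

The two-class LDA accumulates S_W (within-class) and S_B (between-class)
scatter from per-trial, per-frame population vectors; the discriminant is
the leading eigenvector of S_W⁻¹S_B, unit norm, signed so the first class
projects higher. A singular S_W receives a ridge of 10⁻⁶·trace/dim with a
warning. For two classes this equals S_W⁻¹(m₁ − m₂) up to scale — verified
against that closed form, a 1°-grid exhaustive search, and scikit-learn.

The windowed SNR divides the mean absolute projected separation of the two
compared conditions within a 50-frame window by the root of the
session-total within-class projected variance of those conditions. The
discriminant is always trained on the correct-right vs correct-left
contrast, refit per window by default (a fit-once option exists).
Same-stimulation pairs are LL↔LR and RR↔RL; same-response pairs LL↔RL and
RR↔LR (first letter stimulus, second response); the two pairings are
averaged and the series normalized to its session maximum. The SNR is a
ratio along the discriminant and is invariant to any common invertible
linear map of the population vectors — a property test.

SVM decoding uses `sklearn.svm.SVC(kernel="linear", C=1.0)` on window-mean
(8-frame) population vectors, trained on a stratified random 70% of correct
trials labeled by stimulus, averaged over 10 repeats, and scored on
held-out correct trials, on error trials labeled by stimulus and by
response, and on a label-shuffled control. Native-space correlations use
trial-averaged neuron × time vectors per bin (six 25-frame bins starting at
frame 20, or a sliding 15-frame window): within-correct correlates random
50/50 splits of correct trials (averaged over 100 splits), correct-vs-error
correlates the correct mean against the same-stimulus error mean, each per
direction and then averaged.

## The synthetic generator

The generator is the package's study-condition definition, not a tuning
surface. Defaults, chosen once: 60 neurons, 60 trials, error rate 0.3
(sessions near a 70% performance criterion), ΔF/F amplitude β = 1 per
event, Gaussian noise σ = 0.15, population mixture 10% sample-right, 10%
sample-left, 15% delay-right, 15% delay-left, 5% reward-right, 5%
reward-left, the rest unselective — delay-selective neurons the most
abundant group and roughly half the population task-selective. Trial
directions are balanced (|#left − #right| ≤ 1) and pseudo-randomly ordered;
errors are drawn per direction at the stated rate, always leaving at least
two correct trials per side. Reaction times are independent jitter
(0.15 ± 0.03 s, clipped positive), so the RT-vs-coding-direction
correlation is null by construction unless a user plants one.

Selective neurons fire one event per matching trial; event times tile each
phase in neuron order (the sequence structure), stopping one decay
half-life (ln 2·τ_d, clipped to half the window) before the phase end.
The margin is an identifiability constraint, not cosmetics: an event in the
final ~0.7 s of a phase produces fluorescence mostly inside the *next*
phase's window, and no fluorescence-based classifier could attribute it to
the planted phase, so planted labels would not be recoverable even at zero
noise. Sample neurons follow the stimulus, reward neurons the response
side. Error-trial drift applies to delay-selective neurons only: from delay
onset, noiseless activity is the convex mixture
(1 − w(t))·a_stim + w(t)·a_opposite with w(t) = clip(drift_rate·t_delay, 0, 1)
and `drift_rate` in units of s⁻¹. Per-second units make the drift
magnitude independent of the frame rate and let moderate rates cross the
midpoint within a 1.5–2-s delay — at 0.5 s⁻¹ the mixture reaches ~0.83 by
the delay's end, which is what produces a *negative* late-delay TSI rather
than a saturating 0. Transients are truncated at trial boundaries (trials
are independent). Pixel movies paint each neuron's trace onto a compact
footprint (default 4 × 4 px) on a non-overlapping grid, with optional
background noise on every pixel; explicit overlapping positions warn and
record an overlap map.

What the generator does *not* emulate: correlated noise across neurons or
time, baseline drift and bleaching, motion artifacts, licking kinematics,
arousal covariates, overlapping spatial footprints, or raw-fluorescence to
ΔF/F conversion. Passing tests therefore show that the analysis chain
recovers the structure this model plants under white noise — not that it is
robust to the full noise structure of real recordings. The delay analysis
window is fixed at frames [120, 170) regardless of the nominal 1.5-s or
2-s delay duration recorded per trial; the duration column is metadata for
subgroup reruns.

## Numerical conventions and degenerate inputs

- auROC of two identical constant distributions is 0.5 (index 0) by the
  midrank convention.
- t-test with k < 2 events raises; rank-deficient templates raise and name
  the coinciding event frames.
- TSI at dPP = dOO = 0 is NaN (reported missing), never ±∞.
- Zero-variance neurons in Z-scoring get a σ floor of 10⁻¹² and are
  flagged on the model object.
- Degenerate coding modes (zero activity difference) raise rather than
  returning an arbitrary unit vector.
- Pipeline outputs are byte-reproducible: every stochastic stage takes an
  explicit seed, trial tables round-trip through CSV at %.17g with
  round-trip float parsing, and the run manifest records SHA-256 checksums
  of all outputs.

## Problem sizes used in the validation suite

The test suite and benchmark script run at the generator defaults (60
neurons × 60 trials) for the drift-signature analyses, 10,000 simulated
pixels for t-test calibration, 1,000 simulated neurons for the PI null,
10⁶ random pairs for the TSI bound, and 100 split-PCA iterations — sizes at
which every stochastic check is stable across seeds on a single CPU in a
few minutes.

## Known limitations

- The six-regressor GLM assumes the three phase windows tile the trial; a
  task with variable-length delays would need per-trial windows.
- The per-event amplitude model assumes at most one transient per event
  window; burst responses inflate single-event amplitudes rather than
  splitting them.
- Cross-session aggregation (pooling neurons across sessions after
  per-session trial-averaging) is supported by concatenating label tables
  but not exercised by the synthetic generator, which emits single
  sessions.
- The SVM and LDA analyses use all simultaneously recorded neurons without
  regularization beyond the SVM's C and the LDA ridge fallback; populations
  much larger than the trial count would need explicit shrinkage.
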