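# Methods

## The decoding problem

The package decodes a binary move-vs-rest state from multichannel
intracranial (sEEG) recordings in which all contacts in or near primary
(sensori-)motor cortex have been removed. The working hypothesis is that
movement-related information is distributed: no single remaining area drives
performance, but the *joint second-order statistics* of many channels do.
The decoder therefore never looks at mean evoked responses — a trial is
represented purely by the covariance matrix of its band-limited amplitude
envelopes in a low-dimensional component space.

## Pipeline

1. **Motor-label exclusion.** Any channel whose anatomical label contains
   "motor" or "central" (case-insensitive substring, so precentral,
   postcentral and paracentral labels are caught too) is removed before
   anything else.
2. **Noise QC.** Channels are flagged for excess line noise when their
   50 ± 2 Hz Welch band power strictly exceeds Q3 + 2·IQR of the
   cross-channel power distribution, and for abnormal amplitude when the
   z-score (sample SD) of log mean-square amplitude exceeds 1.6449
   (one-sided p < 0.05 under a normal assumption, no multiple-testing
   correction). The upper-fence reading of the "two times the interquartile
   range" rule was chosen because a literal `power > 2·IQR` threshold is
   scale-dependent and flags every channel when the spread is small; the
   strict inequality means identical channels are never flagged.
3. **Filtering.** Retained channels are linearly detrended, demeaned, and
   band-stop filtered at 50/100/150/200 Hz (zero-phase FIR, ±2 Hz notch
   width, Hamming-windowed design via MNE). Notches at or above Nyquist are
   skipped with a warning.
4. **Envelopes.** Beta (12–30 Hz) and high-gamma (55–90 Hz) envelopes are
   the magnitude of the analytic (Hilbert) signal of the band-passed data;
   transition bandwidth 25 % of each band edge. Envelopes are not decimated.
5. **Epoching.** One 3 s epoch per cue, starting exactly at cue onset (no
   baseline offset). Left- and right-hand trials merge into a single move
   class; the combined band stacks the beta block then the high-gamma block
   along the channel axis, doubling the input dimension.
6. **Per-fold transform.** Stratified, shuffled, seeded 10-fold CV.
   Within a fold, per-channel z-scoring statistics and a PCA basis are
   fitted on the training trials' concatenated samples only. Zero-variance
   channels get std 1 with a warning; component signs are fixed by making
   each component's largest-magnitude loading positive; component counts
   above the channel dimension are clipped with a warning (mirroring a
   participant with fewer contacts than the largest grid value).
7. **Covariances.** Each trial's component-space samples give a sample
   covariance shrunk by the closed-form Ledoit-Wolf estimator
   (1−ρ)S + ρ·(tr S/k)·I, implemented from scratch (it is the quantity the
   decoder lives on) and cross-checked against an independent
   implementation in the tests. Shrinkage keeps trial covariances SPD even
   when the component count approaches the number of samples per trial.
8. **Classification.** Minimum distance to mean on the SPD manifold under
   the symmetrized Kullback–Leibler (Jeffreys) divergence. The class
   centroid is computed in closed form as the matrix geometric mean of the
   class's arithmetic (A) and harmonic (H) covariance means,
   M = A^{1/2}(A^{−1/2} H A^{−1/2})^{1/2} A^{1/2}, rather than by fixed-point
   iteration: this is exact for the Jeffreys centroid and removes an
   iteration-tolerance knob. Matrix roots use eigendecompositions with
   eigenvalues floored at 1e−12, and every composite result is re-symmetrized
   as (M + Mᵀ)/2. One-sided divergences are available too, paired with their
   matching centroids (left-KL → arithmetic mean, right-KL → harmonic mean);
   the symmetric variant is the default because a distance-based classifier
   wants a symmetric discrepancy. The continuous decision value is
   d(c, mean_rest) − d(c, mean_move), so positive scores mean "move" — a
   sign convention needed to compute AUC. Exact ties resolve to rest, the
   null class.
9. **Evaluation.** AUC is computed per test fold and averaged. Participant
   mean AUCs are tested against 0.5 with a two-sided one-sample t-test
   (two-sided because chance is a point null), Bonferroni-corrected over the
   66 cells of the full 2-task × 3-band × 11-component design. Paired
   condition comparisons use the Wilcoxon signed-rank test, exact for
   n ≤ 25 without ties, normal approximation with continuity correction
   otherwise. Channel contributions to the first principal component are
   reported as |loading| × explained-variance ratio (absolute loadings by
   default; squared loadings available).

The CSP-LDA baseline shares the CV harness: class covariances are the
average of Ledoit-Wolf-regularized per-trial covariances, filters come from
the generalized eigenproblem C_move w = λ(C_move + C_rest) w taken
alternately from the two ends of the spectrum, features are per-trial
average power of the filtered signals (not log power, with a log option),
and the discriminant is an LDA with the least-squares solver and no
shrinkage.

## Synthetic sessions

The generator emulates the cued grasping protocol: 3 s move / 3 s rest
blocks, 30 cues per hand per task, executed and imagined tasks back to back,
with 2 s lead-in and 1 s tail padding and no inter-trial jitter (the
protocol is fixed-schedule). Channel counts default to the clinical 42–125
range; the sampling rate defaults to 1024 Hz — typical of the amplifier
class used for such recordings, and not otherwise constrained — and is
configurable.

The class signal is a second-moment effect only: `n_latent` band-limited
unit-variance Gaussian sources (alternately beta and high-gamma) are scaled
during move epochs by 1/√(1+snr_move) (beta, desynchronization-like) or
√(1+snr_move) (high-gamma, synchronization-like), mixed into channels
through a random Gaussian matrix with column scale 1/√n_latent, plus
unit-variance white sensor noise. `snr_move = 0` is an exact null; the
default `snr_move = 4` produces clearly separated class trajectories in the
leading components. Line noise is added as 50/100/150/200 Hz sinusoids with
random per-channel phases; designated bad channels get 10× line amplitude
or a 5× overall gain; a configurable fraction of channels receives
motor/central anatomical labels from a built-in Destrieux-style list that
also includes "white matter" and "Unknown" entries. Amplitudes are arbitrary
units. Identical seeds give bit-identical sessions.

What the generator does **not** emulate: 1/f broadband spectra, epileptiform
transients, electrode geometry, non-stationarities, or any evoked (mean)
response. Passing tests therefore demonstrate that the pipeline recovers
class-dependent covariance structure and stays calibrated under a null —
not that the specific AUC levels transfer to patient recordings.

## Problem sizes in tests and experiments

The test suite and the reproduction script run the *complete protocol*
(60 move + 60 rest trials, 10-fold CV) on scaled sessions: 24–36 channels,
256 Hz sampling, executed task only. These sizes are the package's own
choice for desk-scale reproducibility; the per-trial statistics the decoder
sees (3 s envelope epochs, balanced classes) are unchanged, and 256 Hz
comfortably resolves the 90 Hz upper band edge. Null calibration uses 100
sessions at 10 components on the beta band; signal recovery uses rank-5
planted differences decoded at 3/10/25 components and compared against
CSP-LDA at 10 filters.

## Numerical choices and degenerate inputs

- SPD validation: symmetry to 1e−10 relative tolerance, all eigenvalues
  strictly positive; constant trials raise "degenerate covariance".
- KL divergence uses Cholesky solves and slogdet (never explicit inverses
  or determinants).
- Fewer than 4 channels: the IQR-based line-noise rule refuses to flag and
  warns. Silent (all-zero) channels are excluded from the amplitude
  distribution and never flagged by it.
- Fold construction requires at least one trial of each class in training;
  a single-class training fold is an error, not a silent skip.
- Recording I/O uses a compressed NumPy bundle plus a BIDS-style events TSV
  (`onset`, `duration`, `trial_type`, plus `hand`/`task`/`onset_sample`).

## Known limitations

- The KL variant actually used by practitioners varies; results can differ
  slightly between the symmetric and one-sided variants, which is why all
  three are selectable and sweepable.
- The covariance representation discards evoked responses by design; a task
  with a strong mean component would be under-decoded.
- Trial-based evaluation only; no online/causal variant.
- Re-referencing is out of scope: recordings are assumed already referenced
  (clinically, to a quiet white-matter contact).
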