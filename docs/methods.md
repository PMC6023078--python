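# Methods

## Scope and data model

The package classifies *breath patterns* (BPs): 10 s mono acoustic windows
(22,050 Hz) in which a user deliberately modulates breathing, preceded by a
1 s signal-free lead. Each user defines a small vocabulary (default four
classes, each mapped to a phrase) and records 10 training repetitions per
class; live inputs are single 10 s windows classified against the resulting
template library. No public corpus of such recordings exists, so the
package ships a first-class synthetic generator that reproduces this
acquisition protocol; all quantitative claims in the test suite are claims
about that synthetic world.

## Wiener enhancement

Noise is assumed additive and stationary over the window, with the leading
second guaranteed signal-free by the acquisition protocol; the noise power
spectrum is the mean periodogram over the analysis frames wholly inside
that lead (at least two frames are required, else the input is rejected).
Enhancement applies, per frame `t` and bin `f`, the gain
`W = ξ/(ξ+1)` with the decision-directed a-priori SNR

    ξ(f,t) = α · G(f,t−1)² · γ(f,t−1) + (1−α) · max(γ(f,t) − 1, 0),

initialised with the maximum-likelihood term at the first frame, where
`γ = |X|²/P_noise` is the a-posteriori SNR and `G` the previous frame's
(unfloored) Wiener gain.

Parameter defaults, with rationale (the source system published none):

| parameter | default | why |
|---|---|---|
| frame length | 32 ms (rounded to an even sample count), Hann, 50% hop | standard speech-band analysis; periodic Hann at 50% hop overlap-adds to exactly 1, so resynthesis is exact to float rounding |
| α | 0.98 | the canonical decision-directed smoothing constant |
| gain floor | 0.05 (≈ −26 dB) | suppresses musical noise without audible residual pumping |
| noise lead | 1 s | the protocol's guaranteed silent lead; no voice-activity detection is attempted |

Framing is left-aligned (frame `t` covers original samples
`[t·hop − L, t·hop)` after an `L`-sample zero pre-pad), which makes the
"frames wholly inside the lead" bookkeeping explicit. Operations run at the
full 22,050 Hz rate; sub-sampling happens strictly afterwards.

## Envelope extraction

The denoised signal is resampled to 1000 Hz (polyphase FIR, `line` edge
padding so constants survive the boundaries), full-wave rectified,
low-passed with a zero-phase 4th-order Butterworth at 2 Hz, clipped of the
negative ringing the filter introduces, and decimated to 100 Hz (the 2 Hz
low-pass already guarantees anti-aliasing against the 50 Hz envelope
Nyquist). Rectification **before** filtering is essential: a 2 Hz low-pass
applied to zero-mean audio would annihilate the signal; rectification is
the amplitude-demodulation step, and the discard of negative portions is
applied after filtering to remove ringing. The 2 Hz cutoff is a declared
interpretation of an ambiguous printed constant in the source description;
it comfortably covers the 0.2–0.8 Hz physiological breathing band plus the
modulation harmonics that give patterns their shape, and it is
configurable (`cutoff_hz`). Normalisation subtracts the minimum (offset
removal) and scales the peak to 1, independently per envelope — training
and live envelopes are normalised the same self-contained way, so
classification compares shape, not loudness or baseline.

## Distances and classification

Both metrics operate on the 1000-sample normalised envelopes. The
Euclidean distance requires equal lengths and treats a length mismatch as
an error rather than silently resampling (the pipeline guarantees fixed
lengths; silent resampling would mask upstream bugs). DTW uses local cost
`|uᵢ − vⱼ|` (the Euclidean distance between scalar samples), the standard
three-neighbour recurrence, and no global path constraint by default; a
Sakoe–Chiba band is available for speed. Note the attainable warp-path
length range is `max(a,b) ≤ K ≤ a+b−1` — the corner case `K = a+b−1`
(e.g. two length-2 constant series) is legal and produced by the DP.
Backtracking breaks cost ties by preferring the diagonal step, then the
`i`-step; argmin ties in the 1-NN vote break toward the lowest template
index. Both rules are arbitrary but deterministic and order-stable. `k` is
fixed at 1. The DP kernels are numba-compiled; classifying one live
envelope against 40 templates takes ~0.1 s unconstrained.

## Synthetic world

The generator states, once, the world the evaluation runs in:

* A BP class is a sum of 2–5 raised-cosine (Hann-shaped) bumps — smooth,
  non-negative, compactly supported — with centres on a jittered grid in
  [2.5 s, 8.0 s], widths 0.6–1.5 s, amplitudes 0.4–1.0. Classes within a
  subject are drawn to be pairwise distinct beyond the jitter scale.
  Per-repetition jitter: timing ±0.15 s, amplitude ±10%.
* Acoustic rendering multiplies a 200–4000 Hz band-limited Gaussian carrier
  (breath sounds at a close microphone are broadband) by the upsampled
  envelope and adds stationary white background noise scaled to a requested
  SNR, defined as breath power over noise power across the window. Default
  +10 dB: a close-talking cardioid microphone on breath sounds in a quiet
  room. The rendering is peak-bounded at 0.99 full scale.
* Live repetitions are stretched about the centre of their active support
  (uniform ×0.85–1.2) and shifted (uniform ±0.3 s), reproducing the
  observed training-vs-live temporal mismatch. The sampled shift is clamped
  to the interval keeping the warped support inside
  (lead, window end): the protocol guarantees a signal-free lead, which the
  denoiser relies on, so live patterns may not invade it.
* Every recording's RNG stream is keyed by
  `(dataset seed, class, train/live, repetition)`, so outputs are pure
  functions of the seed and survive reordering.
* Outlier flags (subjects who could not recall their chosen pattern) are
  metadata set at generation/ingestion, default all-false; no automatic
  outlier detector is attempted, since the underlying criterion is human
  judgment. Omission granularity is the whole live set (5 repetitions of
  one class for one subject).

What the generator does **not** emulate: physiological airflow dynamics,
inhale/exhale asymmetry, nasal vs oral routing, microphone positioning
variance, non-stationary background noise, or the difficulty real users
have reproducing their own patterns. A green directional test (DTW beats
ED under temporal mismatch) therefore establishes the algorithmic
property, not human-subject performance levels; measured synthetic
accuracies (≈98% DTW vs ≈88% ED over 23 simulated subjects) are expected
to sit above the published human results while preserving their ordering
and per-class structure.

## Evaluation conventions

Per subject: a true-class × predicted-class confusion matrix over the
evaluated live patterns and the percentage correct out of those evaluated
(20 when nothing is omitted). Aggregation sums confusion matrices
element-wise; flagged sets are excluded exactly once, at the subject stage.
Because "average rate" is ambiguous, both the mean of per-subject
percentages and the pooled trace/total percentage are reported and
labelled. No single number is labelled "reliability": per-class success
rates are exposed instead, as the derivation of such a headline figure is
not reconstructible. No significance testing of the ED/DTW gap is done.

## Numerical choices and degenerate inputs

* Identity warp (stretch 1, shift 0) short-circuits to an exact copy.
* All-zero envelopes: normalisation returns them unchanged; rendering
  produces background noise at a fixed reference power; classification
  still answers (1-NN is total).
* Noise PSD is floored at `max(psd) · 1e−20` so an all-zero lead cannot
  divide by zero.
* Envelope CSVs are written at 17 significant digits, so library
  persistence round-trips float64 bit-exactly.
* Denoised output is clipped to [−1, 1]; per-bin gains never exceed 1, so
  clipping is a formality at the container boundary.

## Known limitations

* The Euclidean-vs-DTW accuracy gap on synthetic data depends on the warp
  range; at stretch ≈ 1 both metrics saturate at 100% (tested as the
  no-warp limit).
* The Wiener stage assumes the lead truly is signal-free; breath energy in
  the lead inflates the noise estimate and over-suppresses the pattern.
* No breath-onset detection: windows are fixed-length files, and shorter or
  longer inputs are zero-padded or truncated (logged), mirroring the
  keypress-triggered acquisition of the original platform.
* FastDTW-style accelerations and >4-class vocabularies are out of scope.
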