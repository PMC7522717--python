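# Methods

## Model and rationale

The package quantifies the alignment of a point process (intonation-unit
onsets) with the phase of a continuous signal (the speech envelope). The
underlying picture: spontaneous speech is delivered as a succession of
syllables (~5 Hz amplitude modulation), and syllables group into
intonation units (IUs) whose onsets recur roughly once per second. If
IU sequencing is rhythmic, IU onsets should land at consistent phases of
the envelope's low-frequency components, hierarchically above the
syllabic rhythm. Phase consistency is the appropriate statistic because
it is invariant to the envelope's amplitude and, in the pairwise form
used here, unbiased by the number of events per speaker.

## Envelope extraction

- Filterbank: `n_bands` (default 10) Butterworth band-passes of order 4,
  applied forward–backward (zero phase), with cut-offs equally spaced on
  the Greenwood position–frequency map of the human cochlea,
  f(x) = 165.4·(10^{2.1x} − 1) Hz with x the fractional distance from the
  apex. Default span 100–8000 Hz. Zero-phase filtering matters because
  the downstream analysis reads phases off this signal; a causal filter
  would add frequency-dependent delays.
- Narrowband envelopes are magnitudes of the analytic (Hilbert) signal;
  their across-band average is the wideband envelope.
- Anti-alias low-pass (Butterworth order 8, zero phase) at 0.4 × the
  envelope rate, then linear-interpolation resampling to `env_rate_hz`
  (default 100 Hz, so a 2-s window holds exactly 200 samples and the
  spectral bins fall at multiples of 0.5 Hz). Filtering can leave tiny
  negative excursions; these are clipped to 0 before normalization.
- `unit_max` normalization (divide by the recording's maximum) is the
  default because the trough-magnitude threshold of 0.01 is defined on a
  0–1 scale. Silent input is returned as all-zeros with a warning
  rather than dividing by zero.

## Phase-consistency spectra

- Windows span [onset − w/2, onset + w/2) with w = 2 s by default
  (optionally 4 s for 0.25 Hz resolution at the cost of more dropped
  boundary onsets). Onsets are snapped to the nearest envelope sample
  (≤ 5 ms error at 100 Hz, negligible below 5 Hz). Windows crossing the
  recording bounds are dropped and counted; there is no zero padding.
- Per window: demean, multiply by one full-length symmetric Hann taper,
  FFT without padding, take the phase at bins k/w Hz, k = 1 … Nyquist−1
  (DC excluded). A bin whose tapered amplitude is below 1e−12 has no
  defined phase; that event is dropped from that bin only.
- PPC per bin over a speaker's events via the O(N) identity
  ((Σcos θ)² + (Σsin θ)² − N) / (N(N−1)), verified in tests against the
  O(N²) pairwise definition. Speakers need strictly more than 5 retained
  onsets.
- Windows are cut from the shared recording envelope, so stretches where
  another participant speaks inside a window are retained by design;
  turn-taking overlap is part of the signal, not an artifact.
- Group spectrum: unweighted mean over speakers (speakers are the unit
  of analysis regardless of IU count). Uncertainty: percentile bootstrap
  over speakers, 1000 resamples, 2.5/97.5 percentiles. The percentile
  method was chosen as the simplest CI that respects the bounded,
  skewed distribution of PPC; with one speaker it degenerates to the
  estimate itself.

## Permutation null and FDR

- Troughs: local minima of the unit-scaled envelope with prominence
  ≥ `min_magnitude` (default 0.01) and pairwise separation
  ≥ `min_separation_s` (default 0.2 s, the average syllable duration).
  "Minimum magnitude" is read as topographic prominence — depth relative
  to the surrounding envelope — rather than an absolute ceiling on the
  minimum's value; both the threshold and the reading are configurable
  at the call site. Thinning is greedy deepest-first (the deepest trough
  in any conflicting set wins), implemented via `scipy.signal.find_peaks`
  on the negated envelope, whose `distance` rule removes lower-priority
  peaks first; tests pin this against an independent enumeration.
  Separations exactly at the bound are kept.
- Surrogates: each speaker's onsets are replaced by a uniform draw
  without replacement from the troughs of that speaker's own recording,
  preserving the onset count; speakers are permuted independently. This
  is the minimal permutation that respects the per-speaker structure of
  PPC while keeping the syllable-boundary association of onsets.
- The statistic compared against the null is the group (speaker-mean)
  PPC per bin. Per-bin p = (r + 1)/(n_perm + 1) with r the number of
  surrogate group means ≥ the observed one, so p is never 0 and the
  minimal attainable value with 1000 permutations is 1/1001.
- Eligibility is symmetric: a speaker whose recording lacks enough
  usable troughs is excluded from both the observed and the surrogate
  spectra, so both sides of the comparison always use identical data.
- Multiple comparisons across frequency bins (0.5–10 Hz by default) are
  controlled with Benjamini–Hochberg at q = 0.01 (step-up rule, no
  dependency correction), via statsmodels.

## Duration statistics and robustness filter

- Durations are offset − onset, pooled across speakers; histograms use
  50 ms bins normalized to probabilities (the bin grid always covers the
  maximum, so probabilities sum to 1 despite float noise in accumulated
  onset times); the median CI is a percentile bootstrap over pooled IUs
  (1000 resamples).
- The robustness filter retains IU i iff onset_i − offset_{i−1} < 1 s,
  where i−1 is the immediately preceding IU in the original sequence,
  across speakers by default (`same_speaker_only` restricts it); the
  first IU has no predecessor and is dropped. Gaps are computed on the
  original sequence — the filter is a single pass, so removing an IU
  never changes another IU's predecessor. The inter-IU interval is
  offset-to-onset (the pause), not onset-to-onset.

## Synthetic data generator

The generator emulates exactly the features the analysis consumes:

- Syllables are raised-cosine bursts whose support is 1.2 × the syllable
  duration — wide enough to overlap slightly, narrow enough to leave a
  deep trough at every syllable boundary, as vocalic nuclei and
  consonantal boundaries do in real envelopes.
- An IU holds 3–7 syllables (uniform) at 5 Hz; the final syllable is
  lengthened ×1.5 with the penultimate eased halfway, and burst peaks
  decay geometrically to 0.7 of the IU-initial peak. The median
  (5-syllable) IU lasts 1.2 s.
- Onset-to-onset intervals are `iu_period_s` (default 1.0 s) times a
  unit-mean lognormal with CV 0.1, plus an exponential pause (mean
  0.2 s, truncated at 2 s). When an IU outlasts its drawn interval the
  interval is extended to fit (counted and logged) — with the default
  syllable counts this happens for roughly half the IUs, so the realized
  mean interval is ~1.35 s. Most inter-IU gaps are well below 1 s.
- Speakers take turns of geometrically many IUs (mean 3); a uniform
  noise floor (0.005) keeps silence non-degenerate without creating
  troughs that pass the 0.01 prominence threshold.
- `generate_audio` renders the same envelope onto band-passed
  (100–4000 Hz) white noise; the envelope-extraction pipeline recovers
  the designed envelope with correlation > 0.9.
- `null_annotation` places onsets at randomly chosen envelope troughs —
  the complete null in which the permutation distribution is exact by
  exchangeability — for type-I error and FDR calibration.

What the generator does **not** emulate: pitch contours, phonetic
segment structure, amplitude dynamics of real vowels/consonants,
cross-speaker acoustic overlap (speech is sequential by turns),
reverberation and recording noise. Passing tests therefore demonstrate
the correctness and calibration of the estimator and test on signals
with the assumed burst/period structure, not performance on adverse
real-world acoustics.

## Problem sizes

Validation and the reproduction script use 300-s, 4-speaker
conversations (~220 IUs, ~55 per speaker), 10 generator seeds for rhythm
recovery, 1000 permutations for the positive control, and 20 × 200
permutations for null calibration — sizes at which the Monte-Carlo error
of every reported quantity is far below the decision thresholds, while a
full run stays in the seconds range.

## Known limitations

- TextGrid support covers long-format interval tiers only, read-only.
- The envelope resampler is linear interpolation after a zero-phase
  anti-alias filter; for envelope rates far below 100 Hz a polyphase
  resampler would be preferable.
- The permutation test recomputes surrogate spectra from precomputed
  trough phases; memory grows with troughs × bins per recording, which
  is negligible at envelope rates around 100 Hz but worth noting for
  hour-long recordings at high envelope rates.
- Bootstrap CIs use the percentile method throughout; BCa would give
  slightly better small-sample coverage for strongly skewed statistics.
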