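# iurhythm

Tools for asking whether the onsets of **intonation units** (IUs) — the
prosodic chunks that spontaneous speech naturally breaks into — form a
low-frequency (~1 Hz, delta-band) rhythm that is physically present in the
**speech envelope**, the slow amplitude contour of the acoustic signal.

The pipeline treats IU onsets as a point process and the envelope as a
continuous field, and measures their alignment with a point–field
synchronization analysis borrowed from spike–field coupling in
neurophysiology:

1. **Envelope extraction** — audio is band-pass filtered into 10 bands with
   cut-offs equidistant on the human cochlear map (Greenwood function),
   each band's Hilbert magnitude is taken, and the narrowband envelopes are
   averaged into a wideband envelope, low-passed and resampled to 100 Hz,
   scaled to 0–1.
2. **Phase-consistency spectra** — 2-s envelope windows centered on each IU
   onset are demeaned, Hann-tapered and Fourier transformed (0.5 Hz bins;
   4-s windows give 0.25 Hz). At every frequency f, the consistency of the
   phase angles θ₁ … θ_N across a speaker's N onsets is summarized by the
   pairwise phase consistency

   PPC(f) = 2 / (N(N−1)) · Σ_{j<k} cos(θ_j − θ_k),

   an estimator of squared phase-locking strength that is unbiased by N, so
   speakers with different IU counts are comparable. Spectra are computed
   per speaker (> 5 usable onsets) and averaged with equal weights;
   bootstrap over speakers gives a 95% CI.
3. **Trough-constrained permutation test** — every IU onset is necessarily a
   syllable boundary, and syllable boundaries sit at envelope troughs, so
   the null model permutes onsets onto detected troughs (local minima with
   prominence ≥ 0.01 on the 0–1 scale, ≥ 200 ms apart), preserving each
   speaker's onset count. 1000 surrogate group spectra give per-bin
   exceedance p-values, corrected across bins by Benjamini–Hochberg FDR at
   1%.
4. **Duration statistics** — pooled IU durations as 50 ms-bin probability
   histograms, median with a bootstrapped 95% CI, and a robustness filter
   that keeps only IUs following an inter-IU interval < 1 s.

A synthetic-conversation generator produces envelope-like signals with
known ground truth (syllable bursts at ~5 Hz grouped into ~1 s IUs with
IU-initial reset, final lengthening, pauses and turn-taking speakers), so
every stage can be validated end to end.

## Worked example

The `iurhythm` command chains the whole pipeline. On a synthetic 300-s,
4-speaker conversation:

```sh
iurhythm simulate --seed 1 --out-env env.csv --out-ann ius.csv
# wrote 221 IUs over 300.0 s
iurhythm spectrum --env env.csv --ann ius.csv --seed 1 --out spectra
# wrote 4 speaker spectra + group spectrum to spectra
iurhythm test --env env.csv --ann ius.csv --nperm 1000 --seed 1 --out result.csv
# significant bins (FDR 0.01): 0.5 Hz, 1 Hz, 1.5 Hz, ...
iurhythm durations --ann ius.csv --seed 1 --out durations.csv
# median 1.200 s (95% CI 1.200-1.200 s), n = 221
```

The group spectrum peaks at the 1 Hz bin — the designed IU rhythm —
with PPC far above neighbouring bins:

```
frequency_hz,ppc,ci_low,ci_high
0.5,0.8187...,0.7701...,0.8578...
1,0.9725...,0.9660...,0.9787...
```

and the permutation test assigns the peak the smallest attainable p-value,
(0 + 1)/(1000 + 1) ≈ 0.001: none of the 1000 trough-constrained surrogate
onset sets reaches the observed consistency. The median IU duration of
1.2 s is exactly the duration of the generator's median (5-syllable) unit.

Library use mirrors the CLI:

```python
from iurhythm import (SynthConfig, generate_envelope, speaker_spectra,
                      group_spectrum, permutation_test)

env, ann = generate_envelope(SynthConfig(), seed=1)
g = group_spectrum(speaker_spectra(env, ann), seed=1)
res = permutation_test(env, ann, n_perm=1000, seed=1)
```

Real recordings enter through `read_waveform` (WAV) + `compute_envelope`,
and `read_annotations` (CSV with `onset_s, offset_s, speaker_id` columns,
or Praat TextGrid interval tiers, one tier per speaker).

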