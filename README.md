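# usvkit

Detection, classification and group-level statistics for mouse
ultrasonic vocalizations (USVs).

Adult mice emit ultrasonic calls (roughly 40–110 kHz) during courtship
and social investigation, typically recorded for 5-minute sessions at
ultrasonic sample rates (250 kHz by default here). `usvkit` implements a
complete rule-based analysis of such recordings for behavioural
phenotyping — e.g. comparing a knockout line against wild-type
littermates — together with a seeded synthetic-session generator so the
whole chain can be validated against exact ground truth.

## What it computes

**Syllable detection by spectral purity.** For each STFT frame (Hann
window, 512 samples ≈ 2.05 ms, 75 % overlap), the *spectral purity* is
the fraction of total in-band power concentrated in the single most
powerful frequency bin:

```
purity(t) = max_f P(t, f) / Σ_f P(t, f),     f ∈ [25, 120] kHz
```

Narrowband whistles give purity near 1, broadband noise near 1/#bins.
Syllable candidates are maximal runs of frames with purity > 0.15;
candidates separated by silent gaps < 10 ms are merged; extremely short
(< 3 ms) or noisy (mean purity < 0.3) candidates are excluded.

**Call-type classification by pitch jumps.** The *pitch* of a frame is
its dominant (argmax-power) frequency. A *qualifying jump* is a step
between consecutive median-smoothed pitch samples exceeding 4 kHz
downward or 7 kHz upward. Each syllable gets exactly one of seven
labels:

| type | rule |
|------|------|
| NS | no jump, duration < 25 ms |
| NL | no jump, duration ≥ 25 ms |
| JS | one down jump, post/pre duration ratio < 0.4 |
| JN | one down jump, 0.4 ≤ ratio ≤ 2 |
| JL | one down jump, ratio > 2 |
| JU | one up jump |
| MJ | more than one jump |

**Session summaries.** Counts per call type, percentage distribution,
cumulative call duration, and peak frequency (the most powerful
spectrogram cell of each call), per animal and aggregated per group.

**Statistics.** Exact small-sample rank tests — Mann–Whitney *U* and
Wilcoxon signed-rank *V* with p-values from full enumeration of the
null permutation distribution (all C(n₁+n₂, n₁) group assignments, or
all 2ⁿ sign patterns) — and a zero-inflated Poisson mixed model for
per-animal call counts,

```
y_it ~ π·δ₀ + (1−π)·Poisson(exp(x_itᵀβ + b_i)),   b_i ~ N(0, σ_b²),
```

with group × call-type fixed effects and a per-animal random intercept
integrated out by adaptive Gauss–Hermite quadrature.

## Worked example

```python
from usvkit import SessionSpec, synth_session, run_pipeline, mann_whitney_exact

wave, annotations = synth_session(
    SessionSpec(duration_s=10.0, n_syllables=25, snr_db=20.0, seed=7))
calls, summary = run_pipeline(wave, animal_id="m001", group="WT")
print("annotated:", len(annotations), " detected:", len(calls))
print("counts:", {t: c for t, c in summary.counts_by_type.items() if c})
print(f"cumulative duration: {summary.cumulative_duration_s:.3f} s")

res = mann_whitney_exact([5, 7, 8, 9, 10, 11, 12, 13, 14], [1, 2, 3, 4, 6])
print(f"U = {res.statistic:g}, p = {res.p_two_sided:.6f} ({res.method})")
```

prints

```
annotated: 25  detected: 25
counts: {'NS': 2, 'JS': 6, 'JN': 5, 'JL': 2, 'JU': 4, 'MJ': 6}
cumulative duration: 0.884 s
U = 44, p = 0.001998 (enumeration)
```

All 25 synthetic syllables are recovered and typed correctly, and the
enumerated two-sided p-value for the U = 44 configuration at sample
sizes 9 and 5 is 4/2002 ≈ 0.002: only two of the 2002 possible group
assignments give a U at least as extreme in the upper tail.

A command-line interface mirrors the library:
`usvkit simulate | detect | classify | summarize | compare | ranktest`
(see `usvkit --help`).

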