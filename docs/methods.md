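# Methods

## Detection model

The detector assumes mouse USV syllables are narrowband (near-tonal)
frequency-modulated whistles against broadband background noise, so a
single per-frame statistic — spectral purity, the max-bin share of
in-band STFT power — separates call frames from noise frames. Purity is
scale-invariant, which makes the detector insensitive to recording gain.
The chain is: purity thresholding (strict `> 0.15`), merging of
candidates separated by silent gaps strictly below 10 ms, then exclusion
of candidates shorter than 3 ms or with mean purity below 0.3. Merging
precedes the duration filter so that fragments belonging to one call are
rescued before the length test. Strict inequalities at the 0.15 and
10 ms boundaries are pinned by tests; the comparisons carry a 1 ns-scale
epsilon purely to absorb float representation error, never to change
which side of the boundary a value falls on.

### Spectrogram parameters

| parameter | default | why |
|---|---|---|
| sample rate | 250 kHz | Nyquist above the 110 kHz top of the USV band |
| window | Hann, 512 samples (≈ 2.05 ms) | bin width ≈ 488 Hz resolves the 4 kHz jump threshold with ~8 bins of margin; a ≤ 25 ms short call still spans ~40 hops |
| hop | 128 samples (≈ 0.512 ms, 75 % overlap) | boundary resolution of about half a millisecond |
| analysis band | 25–120 kHz | excludes low-frequency cage/handling noise; brackets the 40–110 kHz generated pitch band |
| FFT length | = window (no zero padding) | bins are physical resolution; padding would only interpolate |

Frames lie entirely inside the signal (no edge padding) and are indexed
by their window centres. Argmax ties (pitch, peak frequency) break
toward the lower frequency, deterministically.

### Interval convention

Syllable intervals are half-open `[onset, offset)` in seconds with
`onset` the centre of the first supra-threshold frame and `offset` the
centre of the last (one hop of width for a single-frame run). The first
and last frames of a run typically overlap the call only partially —
their windows extend ±1 ms around the centre, so a window that barely
clips a call edge can already exceed the purity threshold. Extending the
interval by those frames' full widths therefore systematically widens
it, while the span of frame centres is close to unbiased: on generated
sessions at 20 dB SNR the mean onset/offset error is below 0.1 ms
(about a fifth of a hop).

## Classification

Pitch traces are median-smoothed over 3 frames before differencing so a
single mis-tracked frame cannot manufacture two spurious jumps. A
qualifying jump is a consecutive-sample step < −4 kHz (down) or
> +7 kHz (up), both strict — a step of exactly 4.0 or 7.0 kHz does not
qualify. Same-sign qualifying steps within two frames collapse into one
jump (a transition smeared across adjacent frames counts once); the
collapsed jump's magnitude is the total pitch change across the group.
Decision order: ≥ 2 jumps → MJ; one up jump → JU; one down jump →
JS/JN/JL by the duration ratio; no jump → NS/NL by duration.

Two boundary conventions are deliberate design choices, isolated in
configuration:

* **ratio** ≡ post-jump duration / pre-jump duration. The source rule
  table does not define which way the ratio runs; this convention is
  configurable (`ratio_low`, `ratio_high`) and the boundary values 0.4
  and 2.0 both classify as JN.
* **25 ms duration split**: the rule table assigns 25 ms to both the
  short and the long no-jump class; resolved here as NS strictly
  < 25 ms, NL ≥ 25 ms.

The taxonomy has seven labels; candidates removed by the exclusion
rules are simply absent from the output (an implicit "excluded" bucket)
rather than carrying an eighth label.

## Synthetic sessions

The generator emulates 5-minute courtship-type recording sessions:
syllables drawn from the seven archetypes with uniform default type
weights, log-normal silent gaps (median 150 ms, σ = 0.6 — a few calls
per second, typical of courtship bouts), and white Gaussian background
noise. SNR (default 20 dB) is defined as the ratio of the tone's RMS to
the RMS of the noise component inside the analysis band, and the
realized in-band noise RMS matches the specification within 1 %.
Archetype parameters (segment durations, jump sizes, duration ratios)
are sampled away from the classifier's decision boundaries so that
every generated syllable has an unambiguous ground-truth label; gaps
below 12 ms are resampled by default so ground truth is never fused by
the 10 ms merge rule (a flag allows deliberate sub-10 ms gaps for merge
testing). Syllables are rendered as phase-continuous linear-FM tone
segments with 0.5 ms raised-cosine onset/offset ramps.

What the generator does **not** emulate: harmonic stacks and subharmonic
calls, amplitude modulation, reverberation and cage acoustics, overlap
between animals, non-white noise (scratching, bedding), and drifting or
weak calls near the detection threshold. Passing round-trip tests
therefore demonstrates correctness of the algorithmic chain under the
stated signal model, not field performance on arbitrary recordings.

Count tables are drawn from the same process the mixed model assumes:
zero-inflated Poisson with treatment-coded group × call-type log-linear
means (default intercept log 10, group effect 0.5, type and interaction
effects of magnitude ≤ 0.5), mixture zero probability π = 0.3 and
random-intercept SD σ_b = 0.5.

## Exact rank tests

U uses mid-ranks (`U = #{x_i > y_j} + ½·#ties`); V is the positive-rank
sum after dropping zero differences. For combined n ≤ 20 the two-sided
p is `2 · min(tail probabilities)` capped at 1, from the full null
distribution — all `C(n₁+n₂, n₁)` group assignments of the observed
pooled values (conditioning on the tie pattern), or all `2ⁿ` sign
patterns counted by subset-sum recursion over doubled ranks (doubling
makes mid-ranks exact integers). Larger samples switch to the
tie-corrected normal approximation with continuity correction, and the
result is flagged `approximation`. Tests cross-check the enumeration
against an independent exact implementation (scipy's) on hundreds of
random tie-free datasets.

One worked configuration deserves a note: a complete-separation U = 16
at n₁ = n₂ = 4 gives p = 2/70 ≈ 0.029. Published tables sometimes
attach that p to other sample-size pairs for which U = 16 is not
extreme; the enumeration here is the arbiter.

## Zero-inflated Poisson mixed model

The marginal likelihood integrates the per-animal random intercept out
of the product of zero-inflated Poisson row likelihoods:

```
L = Π_i ∫ Π_j [ π·1{y_ij=0} + (1−π)·Pois(y_ij; exp(x_ijᵀβ + b)) ] φ(b; 0, σ_b²) db
```

* **Quadrature**: adaptive Gauss–Hermite with 20 nodes by default. Per
  animal, the posterior mode of `b` is located by a coarse grid over
  ±5σ_b followed by damped Newton steps (the integrand need not be
  log-concave when zeros are inflated, hence the grid safeguard); nodes
  are centred at the mode and scaled by the local curvature. Log-sum-exp
  keeps the node combination stable. Doubling 20 → 40 nodes moves the
  log-likelihood by < 1e-6 on test cohorts.
* **Parameters**: β free, π through a logit (bounded logit ∈ [−15, 15]),
  σ_b direct with bound [0, 5]. σ_b < 1e-8 short-circuits to the
  no-random-effect likelihood, so the σ_b = 0 boundary is exact — with
  σ_b fixed at 0 the fit matches an independent ordinary zero-inflated
  Poisson fit (statsmodels) to < 1e-6 in log-likelihood.
* **Initialization** (fixed, deterministic): β from a least-squares fit
  to `log(y + 0.5)`, π from the excess-zero fraction clipped to
  [0.01, 0.9], σ_b = 0.1.
* **Zero part**: a single intercept-only π; no covariates on the zero
  component. The count family is Poisson; negative binomial is a
  possible extension, not implemented.
* **Standard errors**: central-finite-difference observed information
  over all free parameters, inverted; a singular information matrix
  yields NaN SEs. Parameters ending on a bound (π → 1 for all-zero
  data, σ_b at 0 or 5) set a `boundary` flag on the result.

Calibration: on 20 simulated cohorts of 40 animals × 7 call types
(π = 0.3, σ_b = 0.5), every fixed effect lands within 3 estimated SEs
of its true value in ≥ 90 % of replicates (the truth vector is obtained
by projecting the generator's cell-mean log intensities onto the fitted
treatment-coded design).

## Problem sizes in the test suite

Round-trip validation uses 20 seeded sessions of 50 syllables in 20 s
of audio each at 20 dB SNR — five million samples per session keeps the
full suite fast while every stage still sees thousands of frames per
session. Consistency checks of the count model use ~10,000-row tables;
the calibration uses 20 cohorts of 280 rows. Session duration, syllable
count and cohort sizes are all parameters, so larger runs are one
argument away.

## Known limitations

* Detection is purity-only; very weak calls (SNR near 0 dB) or calls
  masked by tonal noise (e.g. harmonics of cage vibration inside the
  band) will be missed or truncated.
* Pitch is the per-frame argmax: for calls with strong harmonics the
  trace can lock onto the wrong partial; the generator emits no
  harmonics, so this is untested territory.
* The classifier is purely rule-based; it does not model the
  within-type acoustic variability of real repertoires.
* The mixed model assumes a single shared σ_b and Poisson dispersion;
  overdispersed counts will inflate π̂ or σ̂_b rather than be flagged.
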