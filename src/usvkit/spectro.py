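"""STFT spectrograms and per-frame features for ultrasonic vocalizations.

The detector and classifier consume three per-frame quantities computed
here from a magnitude-squared short-time Fourier transform:

* **spectral purity** — the fraction of total in-band power concentrated
  in the single most powerful frequency bin.  Narrowband tonal calls have
  purity near 1; broadband noise has purity near ``1 / n_bins``.
* **pitch** — the dominant (argmax-power) in-band frequency of the frame.
* **total power** — the summed in-band power of the frame.

Defaults (Hann window of 512 samples at 250 kHz, 75% overlap) give a bin
width of ~488 Hz — fine enough to resolve a 4 kHz pitch jump — and a hop
of ~0.512 ms, so even a 3 ms call spans several frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Waveform",
    "SpectrogramFrames",
    "FrameFeatures",
    "compute_spectrogram",
    "frame_features",
    "DEFAULT_WINDOW_MS",
    "DEFAULT_HOP_MS",
    "DEFAULT_BAND_LOW_HZ",
    "DEFAULT_BAND_HIGH_HZ",
]

# 512-sample window / 128-sample hop at the 250 kHz default rate.
DEFAULT_WINDOW_MS = 512 / 250_000 * 1e3
DEFAULT_HOP_MS = 128 / 250_000 * 1e3
# Analysis band: excludes low-frequency cage noise, covers mouse USVs.
DEFAULT_BAND_LOW_HZ = 25_000.0
DEFAULT_BAND_HIGH_HZ = 120_000.0


@dataclass(frozen=True)
class Waveform:
    """Mono sampled audio.

    Parameters
    ----------
    samples
        Real amplitude sequence, dimensionless (typically in [-1, 1]).
    sample_rate_hz
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"waveform must be mono 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate_hz / 2.0


@dataclass(frozen=True)
class SpectrogramFrames:
    """Magnitude-squared STFT of a waveform.

    ``power[i, j]`` is the power of frame ``i`` in frequency bin ``j``;
    ``frame_times_s`` are window centres, strictly increasing;
    ``freq_bins_hz`` is the uniform DFT grid from 0 to Nyquist.
    """

    power: np.ndarray
    frame_times_s: np.ndarray
    freq_bins_hz: np.ndarray
    window_ms: float
    hop_ms: float
    sample_rate_hz: float

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    @property
    def hop_s(self) -> float:
        return self.hop_ms / 1e3

    def frame_index_to_time(self, i: int | np.ndarray) -> float | np.ndarray:
        return self.frame_times_s[i]


@dataclass(frozen=True)
class FrameFeatures:
    """Per-frame purity, pitch and total power inside the analysis band.

    Frames with zero in-band power carry purity 0 and NaN pitch and are
    flagged in ``zero_power``.
    """

    purity: np.ndarray
    pitch_hz: np.ndarray
    total_power: np.ndarray
    zero_power: np.ndarray
    frame_times_s: np.ndarray
    band_low_hz: float
    band_high_hz: float
    hop_ms: float
    window_ms: float = field(default=DEFAULT_WINDOW_MS)

    @property
    def n_frames(self) -> int:
        return len(self.purity)


def compute_spectrogram(
    wave: Waveform,
    window_ms: float = DEFAULT_WINDOW_MS,
    hop_ms: float = DEFAULT_HOP_MS,
    taper: str = "hann",
) -> SpectrogramFrames:
    """Magnitude-squared STFT with frame times at window centres.

    Windows lie entirely inside the signal (no edge padding), so frame
    ``i`` is centred at ``(nperseg/2 + i*hop) / fs`` seconds.  The FFT
    length equals the window length (no zero padding): one bin spans
    ``sample_rate / nperseg`` Hz.

    Raises
    ------
    ValueError
        If the waveform is shorter than one analysis window, or the
        window/hop specification is invalid.
    """
    fs = wave.sample_rate_hz
    nperseg = int(round(window_ms * 1e-3 * fs))
    hop = int(round(hop_ms * 1e-3 * fs))
    if hop <= 0 or nperseg <= 0:
        raise ValueError(f"window ({window_ms} ms) and hop ({hop_ms} ms) must be positive")
    if hop > nperseg:
        raise ValueError(f"hop ({hop_ms} ms) must not exceed window ({window_ms} ms)")
    if len(wave.samples) < nperseg:
        raise ValueError(
            f"waveform of {len(wave.samples)} samples is shorter than one "
            f"{nperseg}-sample analysis window"
        )
    freqs, times, sxx = signal.spectrogram(
        wave.samples,
        fs=fs,
        window=signal.get_window(taper, nperseg) if taper != "boxcar" else "boxcar",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        nfft=nperseg,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    return SpectrogramFrames(
        power=np.ascontiguousarray(sxx.T),
        frame_times_s=times,
        freq_bins_hz=freqs,
        window_ms=nperseg / fs * 1e3,
        hop_ms=hop / fs * 1e3,
        sample_rate_hz=fs,
    )


def frame_features(
    spec: SpectrogramFrames,
    band_low_hz: float = DEFAULT_BAND_LOW_HZ,
    band_high_hz: float = DEFAULT_BAND_HIGH_HZ,
) -> FrameFeatures:
    """Purity, pitch and total power per frame, restricted to a band.

    Purity is the max-bin power divided by the total band power; pitch is
    the frequency of that max bin, ties broken toward the lower frequency.
    Purity and pitch are invariant to rescaling the waveform by any
    nonzero constant.
    """
    if not 0 <= band_low_hz < band_high_hz:
        raise ValueError(f"invalid band [{band_low_hz}, {band_high_hz}] Hz")
    nyq = spec.freq_bins_hz[-1]
    if band_high_hz > nyq + 1e-9:
        raise ValueError(f"band_high_hz {band_high_hz} exceeds Nyquist {nyq}")
    in_band = (spec.freq_bins_hz >= band_low_hz) & (spec.freq_bins_hz <= band_high_hz)
    if not in_band.any():
        raise ValueError("analysis band contains no frequency bins")
    band_power = spec.power[:, in_band]
    band_freqs = spec.freq_bins_hz[in_band]
    total = band_power.sum(axis=1)
    # argmax returns the first (lowest-frequency) max bin: the tie rule.
    argmax = np.argmax(band_power, axis=1)
    peak = band_power[np.arange(len(argmax)), argmax]
    zero = total <= 0.0
    purity = np.zeros_like(total)
    np.divide(peak, total, out=purity, where=~zero)
    pitch = band_freqs[argmax].astype(np.float64)
    pitch[zero] = np.nan
    return FrameFeatures(
        purity=purity,
        pitch_hz=pitch,
        total_power=total,
        zero_power=zero,
        frame_times_s=spec.frame_times_s,
        band_low_hz=band_low_hz,
        band_high_hz=band_high_hz,
        hop_ms=spec.hop_ms,
        window_ms=spec.window_ms,
    )
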