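"""Short-time Fourier transform feature maps for labeled EEG windows.

Each 5-s window x̄(t) becomes a per-channel time-frequency magnitude map
x(ω, u) = |Σ_t x̄(t) g(t−u) e^{-jωt}|, computed on tapered frames at hop
spacing with a real FFT.  Complex phase is discarded: the downstream
autoencoder consumes real-valued maps.  Defaults follow standard EEG
spectrogram practice — 1-s Hann frames at 256 Hz with 50% overlap, giving
1-Hz frequency resolution across the clinical bands — since these are not
physiologically constrained choices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import get_window

from .labeling import LabeledWindow, WindowSet

__all__ = ["StftConfig", "Spectrogram", "stft_map", "crop_bands",
           "batch_spectrograms", "flatten_batch"]


@dataclass(frozen=True)
class StftConfig:
    frame_len: int = 256
    hop: int = 128
    window_fn: str = "hann"
    magnitude: str = "log_magnitude"    # or "magnitude"
    log_floor: float = 1e-8
    freq_crop_hz: tuple[float, float] | None = None
    standardize: bool = True            # zero-mean/unit-variance per map

    def __post_init__(self):
        if not (0 < self.hop <= self.frame_len):
            raise ValueError("need 0 < hop <= frame_len")
        if self.magnitude not in ("magnitude", "log_magnitude"):
            raise ValueError(f"unknown magnitude mode {self.magnitude!r}")


@dataclass
class Spectrogram:
    """Per-channel magnitude STFT: values are channels x F x T."""

    values: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    label: int | None = None
    patient_id: str | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite spectrogram values")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequencies must be ascending")


def _frame_stft(data: np.ndarray, cfg: StftConfig, rate: float):
    """Magnitude STFT of channels x N data via framing + rfft."""
    n = data.shape[-1]
    if n < cfg.frame_len:
        raise ValueError(f"window of {n} samples shorter than frame_len "
                         f"{cfg.frame_len}")
    g = get_window(cfg.window_fn, cfg.frame_len)
    n_frames = 1 + (n - cfg.frame_len) // cfg.hop
    idx = (np.arange(cfg.frame_len)[None, :]
           + cfg.hop * np.arange(n_frames)[:, None])
    frames = data[..., idx] * g                      # ch x T x frame_len
    mag = np.abs(np.fft.rfft(frames, axis=-1))       # ch x T x F
    mag = np.moveaxis(mag, -1, -2)                   # ch x F x T
    freqs = np.fft.rfftfreq(cfg.frame_len, d=1.0 / rate)
    times = (cfg.hop * np.arange(n_frames) + cfg.frame_len / 2) / rate
    return mag, freqs, times


def stft_map(win: LabeledWindow, cfg: StftConfig, rate: float) -> Spectrogram:
    """Time-frequency feature map of one labeled window."""
    mag, freqs, times = _frame_stft(win.data, cfg, rate)
    if cfg.magnitude == "log_magnitude":
        mag = np.log(mag + cfg.log_floor)
    spec = Spectrogram(values=mag, freqs_hz=freqs, times_s=times,
                       label=win.label, patient_id=win.patient_id)
    if cfg.freq_crop_hz is not None:
        spec = crop_bands(spec, cfg.freq_crop_hz)
    if cfg.standardize:
        v = spec.values
        spec.values = (v - v.mean()) / (v.std() + 1e-12)
    return spec


def crop_bands(spec: Spectrogram, keep_hz: tuple[float, float]) -> Spectrogram:
    """Retain only frequency rows inside the closed interval ``keep_hz``."""
    low, high = keep_hz
    if low >= high:
        raise ValueError("need low < high")
    mask = (spec.freqs_hz >= low) & (spec.freqs_hz <= high)
    if not mask.any():
        raise ValueError(f"crop ({low}, {high}) Hz removes all rows")
    return replace(spec, values=spec.values[:, mask, :],
                   freqs_hz=spec.freqs_hz[mask])


def batch_spectrograms(ws: WindowSet, cfg: StftConfig) -> list[Spectrogram]:
    """STFT of every window of a set, order preserved, shapes identical."""
    return [stft_map(w, cfg, ws.rate) for w in ws.windows]


def flatten_batch(specs: list[Spectrogram]) -> tuple[np.ndarray, np.ndarray]:
    """Stack spectrograms into an n x (C*F*T) design matrix plus labels."""
    if not specs:
        return np.empty((0, 0)), np.empty((0,), dtype=int)
    X = np.stack([s.values.ravel() for s in specs])
    y = np.array([s.label for s in specs], dtype=int)
    return X, y
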