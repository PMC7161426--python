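"""Morlet wavelet time-frequency tensorization of multichannel evoked signals.

The frequency grid follows the period grid of the analysis band: wavelet
frequencies 1000/k Hz for integer periods k = 66..265 ms, i.e. exactly 200
bins between 3.77 Hz (1000/265) and 15.15 Hz (1000/66), covering the theta
and alpha bands.  The transform itself is mne's FFT-based complex Morlet
(constant-Q, configurable number of cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .tensor import Tensor3, ho_norm

__all__ = ["TFRConfig", "TFRTensor", "band_frequencies", "morlet_tfr",
           "build_tfr_tensor", "normalize_tensor"]


def band_frequencies(period_range_ms=(66, 265)) -> np.ndarray:
    """Ascending wavelet frequencies 1000/k Hz for integer periods k in the band."""
    lo, hi = period_range_ms
    periods = np.arange(hi, lo - 1, -1)  # descending periods -> ascending freqs
    return 1000.0 / periods


@dataclass
class TFRConfig:
    sample_rate_hz: float = 1000.0
    wavelet_cycles: float = 7.0
    band_period_range_ms: tuple = (66, 265)
    decim: int = 1  # time-axis decimation applied after the transform

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.wavelet_cycles <= 0:
            raise ValueError("wavelet_cycles must be positive")

    @property
    def freqs_hz(self) -> np.ndarray:
        return band_frequencies(self.band_period_range_ms)


@dataclass
class TFRTensor:
    """Frequency x time x channel complex wavelet-coefficient tensor."""

    tensor: Tensor3
    freq_axis_hz: np.ndarray
    time_axis_ms: np.ndarray
    channel_labels: list
    modality: str = ""

    def __post_init__(self):
        f, t, c = self.tensor.dims
        if len(self.freq_axis_hz) != f or len(self.time_axis_ms) != t \
                or len(self.channel_labels) != c:
            raise ValueError("axis lengths must match the tensor dims")
        if np.any(np.diff(self.freq_axis_hz) <= 0):
            raise ValueError("frequency axis must be strictly increasing")


def morlet_tfr(signal: np.ndarray, cfg: TFRConfig) -> np.ndarray:
    """Complex Morlet coefficients of one channel: (n_freqs, n_times).

    2-D input (n_channels, n_times) returns (n_channels, n_freqs, n_times).
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    freqs = cfg.freqs_hz
    # the longest wavelet (lowest frequency, +-5 sigma_t support) must fit
    min_len = int(np.ceil(10.0 * cfg.wavelet_cycles / (2 * np.pi * freqs[0])
                          * cfg.sample_rate_hz))
    if sig.shape[1] < min_len:
        raise ValueError(
            f"signal length {sig.shape[1]} shorter than the longest wavelet "
            f"support (~{min_len} samples at {freqs[0]:.2f} Hz)"
        )
    coeffs = tfr_array_morlet(sig[np.newaxis], sfreq=cfg.sample_rate_hz,
                              freqs=freqs, n_cycles=cfg.wavelet_cycles,
                              output="complex", decim=cfg.decim, verbose="error")
    out = coeffs[0]  # (n_channels, n_freqs, n_times)
    # flatten the filterbank peak gain: L2-normalized constant-Q wavelets have
    # tone gain ~ sqrt(sigma_t) ~ 1/sqrt(f), which would bias spectral peaks
    # toward low frequencies; rescale so a pure tone peaks at its nearest bin
    out = out * np.sqrt(freqs / freqs[0])[None, :, None]
    return out if np.asarray(signal).ndim == 2 else out[0]


def build_tfr_tensor(signals: np.ndarray, cfg: TFRConfig, channel_labels,
                     modality: str = "", exclude=()) -> TFRTensor:
    """Wavelet-transform every channel and stack into frequency x time x channel.

    ``signals`` is (n_channels, n_times); channels listed in ``exclude`` are
    dropped from the tensor (the expert-labeled bad-channel list).
    """
    signals = np.asarray(signals, dtype=float)
    channel_labels = list(channel_labels)
    if signals.shape[0] != len(channel_labels):
        raise ValueError("one label per channel required")
    keep = [i for i, lab in enumerate(channel_labels) if lab not in set(exclude)]
    if not keep:
        raise ValueError("all channels excluded")
    coeffs = morlet_tfr(signals[keep], cfg)  # (n_keep, n_freqs, n_times)
    data = np.moveaxis(coeffs, 0, 2)  # frequency x time x channel
    n_times = data.shape[1]
    time_ms = np.arange(n_times) * cfg.decim / cfg.sample_rate_hz * 1000.0
    return TFRTensor(
        tensor=Tensor3(data, ("frequency", "time", "channel")),
        freq_axis_hz=cfg.freqs_hz,
        time_axis_ms=time_ms,
        channel_labels=[channel_labels[i] for i in keep],
        modality=modality,
    )


def normalize_tensor(t: TFRTensor) -> TFRTensor:
    """Scale to unit higher-order norm (makes fT and uV scales compatible)."""
    norm = ho_norm(t.tensor)
    if norm == 0:
        raise ValueError("cannot normalize a zero tensor")
    return TFRTensor(Tensor3(t.tensor.data / norm, t.tensor.mode_names),
                     t.freq_axis_hz, t.time_axis_ms, list(t.channel_labels),
                     t.modality)
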