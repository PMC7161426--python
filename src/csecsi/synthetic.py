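"""Synthetic MEG-EEG-like photic-driving sessions with known ground truth.

The generator emulates averaged evoked responses to intermittent photic
stimulation: each planted component is a narrowband oscillation with an
onset/plateau/offset envelope tied to the stimulation train, an "occipital"
unimodal topography over an abstract channel-index geometry (no sensor layout
is shipped; real layouts are pluggable through metadata), shared frequency
content across the two modalities, and additive white Gaussian noise scaled
per modality to an exact requested SNR.  The stimulation train defaults to 40
periods at the stimulation frequency, matching the averaged-train duration of
the acquisition protocol it emulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import SessionConfig

__all__ = ["PlantedComponent", "SessionTruth", "gen_session", "gen_truth_presets",
           "PAPER_FRACTIONS"]

BAND_HZ = (3.77, 15.16)
PAPER_FRACTIONS = (0.40, 0.45, 0.50, 0.55, 0.60, 0.70, 0.80, 0.90, 0.95,
                   1.00, 1.05, 1.10, 1.30)


@dataclass
class PlantedComponent:
    center_freq_hz: float
    bandwidth_hz: float = 0.2  # slow AM sidebands around the carrier
    envelope_ms: tuple = (1000.0, None, 1000.0)  # onset, plateau (None = rest), offset
    topo_center: tuple = (0.8, 0.8)  # fractional channel-index position per modality
    topo_width: float = 0.15  # fractional width of the Gaussian gain profile
    amplitude: tuple = (1.0, 1.0)  # per-modality amplitude (0 = absent in a modality)
    phase: float = 0.0

    def __post_init__(self):
        if not (BAND_HZ[0] <= self.center_freq_hz <= BAND_HZ[1]):
            raise ValueError(
                f"center frequency {self.center_freq_hz:.2f} Hz outside the "
                f"{BAND_HZ[0]}-{BAND_HZ[1]} Hz analysis band"
            )
        on, plateau, off = self.envelope_ms
        if on <= 0 or off <= 0 or (plateau is not None and plateau < 0):
            raise ValueError("envelope durations must be positive")


@dataclass
class SessionTruth:
    components: list
    session: SessionConfig
    snr_db: tuple = (10.0, 10.0)  # (MEG, EEG)
    seed: int = 0
    n_channels: tuple = (102, 128)  # (MEG, EEG) sensor counts
    sample_rate_hz: float = 1000.0
    n_stim_periods: int = 40  # averaged stimulation-train length
    pre_post_ms: tuple = (500.0, 500.0)

    def __post_init__(self):
        if not self.components:
            raise ValueError("need at least one planted component")

    @property
    def duration_ms(self) -> float:
        stim = self.n_stim_periods / self.session.f_s_hz * 1000.0
        return self.pre_post_ms[0] + stim + self.pre_post_ms[1]


def _envelope(t_ms, start_ms, stop_ms, comp: PlantedComponent):
    on, plateau, off = comp.envelope_ms
    stim_len = stop_ms - start_ms
    if plateau is None:
        plateau = max(stim_len - on - off, 0.0)
    total = on + plateau + off
    scale = min(stim_len / total, 1.0)
    on, plateau, off = on * scale, plateau * scale, off * scale
    e = np.zeros_like(t_ms)
    rel = t_ms - start_ms
    rise = (rel >= 0) & (rel < on)
    e[rise] = rel[rise] / on
    flat = (rel >= on) & (rel < on + plateau)
    e[flat] = 1.0
    fall = (rel >= on + plateau) & (rel <= on + plateau + off)
    e[fall] = 1.0 - (rel[fall] - on - plateau) / off
    return e


def _topography(n_channels: int, center_frac: float, width_frac: float) -> np.ndarray:
    idx = np.arange(n_channels) / max(n_channels - 1, 1)
    return np.exp(-0.5 * ((idx - center_frac) / width_frac) ** 2)


def gen_session(truth: SessionTruth):
    """Synthesize one coupled session.

    Returns ``(meg_signals, eeg_signals, metadata)`` with signals of shape
    (n_channels, n_times) and metadata holding channel labels, modality names,
    exclusion lists (empty), sampling rate and the session configuration.
    """
    fs = truth.sample_rate_hz
    n_times = int(round(truth.duration_ms / 1000.0 * fs))
    t = np.arange(n_times) / fs
    t_ms = t * 1000.0
    stim_start = truth.pre_post_ms[0]
    stim_stop = truth.duration_ms - truth.pre_post_ms[1]
    rng = np.random.default_rng(truth.seed)
    out = []
    for mod_idx, (mod, n_ch) in enumerate(zip(("MEG", "EEG"), truth.n_channels)):
        signal = np.zeros((n_ch, n_times))
        for comp in truth.components:
            amp = comp.amplitude[mod_idx]
            if amp == 0:
                continue
            env = _envelope(t_ms, stim_start, stim_stop, comp)
            phase = comp.phase + 2 * np.pi * rng.uniform()
            carrier = np.cos(2 * np.pi * comp.center_freq_hz * t + phase)
            if comp.bandwidth_hz > 0:
                am_phase = 2 * np.pi * rng.uniform()
                carrier = carrier * (1.0 + 0.3 * np.cos(
                    2 * np.pi * comp.bandwidth_hz / 2 * t + am_phase))
            topo = _topography(n_ch, comp.topo_center[mod_idx], comp.topo_width)
            signal += amp * topo[:, None] * (env * carrier)[None, :]
        noise = rng.standard_normal(signal.shape)
        sig_energy = np.sum(signal ** 2)
        if sig_energy > 0:
            noise *= np.sqrt(sig_energy / np.sum(noise ** 2)) \
                * 10 ** (-truth.snr_db[mod_idx] / 20)
        out.append(signal + noise)
    metadata = {
        "sample_rate_hz": fs,
        "modalities": ["MEG", "EEG"],
        "channel_labels": {
            "MEG": [f"MEG{i:03d}" for i in range(truth.n_channels[0])],
            "EEG": [f"EEG{i:03d}" for i in range(truth.n_channels[1])],
        },
        "exclude": {"MEG": [], "EEG": []},
        "f_alpha_hz": truth.session.f_alpha_hz,
        "f_s_hz": truth.session.f_s_hz,
        "f_s_fraction": truth.session.f_s_fraction,
        "seed": truth.seed,
        "snr_db": list(truth.snr_db),
    }
    return out[0], out[1], metadata


def gen_truth_presets(kind: str, f_alpha_hz: float = 10.0,
                      f_s_fraction: float = 1.0, seed: int = 0,
                      snr_db: tuple = (10.0, 10.0),
                      n_channels: tuple = (102, 128)) -> SessionTruth:
    """Preset session truths for the recurring response patterns.

    entrained: component(s) at the stimulation frequency (plus its first
    harmonic when it fits in the band); alpha_intrinsic: one component at the
    individual alpha frequency; theta_intrinsic: at 0.4 f_alpha; mixed: one
    recruited plus one alpha-intrinsic component.
    """
    session = SessionConfig(f_alpha_hz=f_alpha_hz, f_s_fraction=f_s_fraction)
    f_s = session.f_s_hz
    comps = []
    if kind == "entrained":
        comps.append(PlantedComponent(f_s, topo_center=(0.8, 0.8)))
        if 2 * f_s <= BAND_HZ[1]:
            comps.append(PlantedComponent(2 * f_s, topo_center=(0.7, 0.7),
                                          amplitude=(0.6, 0.6)))
    elif kind == "alpha_intrinsic":
        comps.append(PlantedComponent(f_alpha_hz, topo_center=(0.8, 0.8)))
    elif kind == "theta_intrinsic":
        comps.append(PlantedComponent(0.4 * f_alpha_hz, topo_center=(0.6, 0.6)))
    elif kind == "mixed":
        comps.append(PlantedComponent(f_s, topo_center=(0.85, 0.85)))
        comps.append(PlantedComponent(f_alpha_hz, topo_center=(0.55, 0.55),
                                      amplitude=(0.8, 0.8)))
    else:
        raise ValueError(f"unknown preset kind '{kind}'")
    return SessionTruth(components=comps, session=session, snr_db=snr_db,
                        seed=seed, n_channels=n_channels)
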