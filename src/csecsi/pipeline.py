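"""Photic-driving analysis: rank-2 coupled decomposition of MEG/EEG
time-frequency tensors and characterization of the resulting components.

The frequency mode is assumed common between the two modalities.  Each rank-1
component of each modality is summarized by its per-channel field-map, its
frequency and time signatures, the obtained frequency (argmax of the frequency
signature, lowest bin on ties), its weight (the component amplitude on the
unit-norm tensor scale), and a recruited/non-recruited label: recruited iff
the obtained frequency lies within +-5% of the stimulation frequency or within
+-5% of its first harmonic (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .framework import CoupledResult, DecompositionOptions, csecsi, rank_sweep
from .tfr import TFRTensor, normalize_tensor

__all__ = [
    "SessionConfig",
    "ComponentSummary",
    "decompose_session",
    "rms_fieldmap",
    "obtained_frequency",
    "classify_recruitment",
    "component_weight",
    "session_rank_sweep",
    "group_summary",
]


@dataclass
class SessionConfig:
    """Stimulation bookkeeping: individual alpha frequency and the stimulation
    frequency expressed as a fraction of it."""

    f_alpha_hz: float
    f_s_fraction: float
    f_s_hz: float = None

    def __post_init__(self):
        if self.f_alpha_hz <= 0:
            raise ValueError("f_alpha_hz must be positive")
        if self.f_s_hz is None:
            self.f_s_hz = self.f_alpha_hz * self.f_s_fraction
        if self.f_s_hz <= 0:
            raise ValueError("f_s_hz must be positive")


@dataclass
class ComponentSummary:
    modality: str
    component: int
    fieldmap: np.ndarray  # per-channel magnitudes
    freq_signature: np.ndarray
    time_signature: np.ndarray
    obtained_frequency_hz: float
    normalized_frequency: float  # obtained / f_alpha
    weight: float
    recruitment: str  # "recruited" | "non_recruited"
    channel_labels: list = field(default_factory=list)


def rms_fieldmap(signals: np.ndarray) -> np.ndarray:
    """Per-channel root-mean-square over time (the signal's power topography)."""
    signals = np.atleast_2d(np.asarray(signals))
    if signals.size == 0:
        raise ValueError("empty signal array")
    return np.sqrt(np.mean(np.abs(signals) ** 2, axis=-1))


def obtained_frequency(freq_signature, freq_axis) -> float:
    """Frequency-axis value at the argmax of the signature magnitude.

    Ties resolve to the lowest frequency (argmax returns the first index and
    the axis is ascending).
    """
    sig = np.abs(np.asarray(freq_signature))
    axis = np.asarray(freq_axis, dtype=float)
    if sig.size == 0:
        raise ValueError("empty frequency signature")
    if sig.shape[0] != axis.shape[0]:
        raise ValueError("signature and axis lengths differ")
    return float(axis[int(np.argmax(sig))])


def classify_recruitment(f_obtained: float, f_s: float) -> str:
    """Recruited iff within +-0.05 f_s of f_s, or +-0.05*2*f_s of 2*f_s (inclusive)."""
    if f_s <= 0:
        raise ValueError("stimulation frequency must be positive")
    if abs(f_obtained - f_s) <= 0.05 * f_s or abs(f_obtained - 2 * f_s) <= 0.05 * 2 * f_s:
        return "recruited"
    return "non_recruited"


def component_weight(model, component: int) -> float:
    """Amplitude of one rank-1 component (its norm with unit-norm factors)."""
    return float(model.amplitudes[component])


def _summaries(model, tfr: TFRTensor, session: SessionConfig):
    out = []
    order = np.argsort(-model.amplitudes)  # dominant component first
    for rank_pos, r in enumerate(order):
        freq_sig = np.abs(model.factors[0][:, r])
        time_sig = np.abs(model.factors[1][:, r])
        fieldmap = np.abs(model.factors[2][:, r])
        f_obt = obtained_frequency(freq_sig, tfr.freq_axis_hz)
        out.append(ComponentSummary(
            modality=tfr.modality,
            component=rank_pos + 1,
            fieldmap=fieldmap,
            freq_signature=freq_sig,
            time_signature=time_sig,
            obtained_frequency_hz=f_obt,
            normalized_frequency=f_obt / session.f_alpha_hz,
            weight=component_weight(model, r),
            recruitment=classify_recruitment(f_obt, session.f_s_hz),
            channel_labels=list(tfr.channel_labels),
        ))
    return out


def decompose_session(meg: TFRTensor, eeg: TFRTensor, session: SessionConfig,
                      rank: int = 2,
                      options: DecompositionOptions | None = None):
    """Normalize both tensors, run the coupled decomposition (frequency mode
    common), and summarize each rank-1 component of each modality.

    Returns ``(CoupledResult, {"MEG": [...], "EEG": [...]})``.
    """
    if len(meg.freq_axis_hz) != len(eeg.freq_axis_hz) or \
            not np.allclose(meg.freq_axis_hz, eeg.freq_axis_hz):
        raise ValueError("MEG and EEG tensors must share the frequency axis")
    meg_n = normalize_tensor(meg)
    eeg_n = normalize_tensor(eeg)
    result = csecsi(meg_n.tensor, eeg_n.tensor, rank, options)
    summaries = {
        meg.modality or "MEG": _summaries(result.selected[0], meg_n, session),
        eeg.modality or "EEG": _summaries(result.selected[1], eeg_n, session),
    }
    return result, summaries


def session_rank_sweep(meg: TFRTensor, eeg: TFRTensor, ranks=(1, 2, 3),
                       options: DecompositionOptions | None = None) -> pd.DataFrame:
    """Reliability-based rank control on the normalized session tensors."""
    meg_n = normalize_tensor(meg)
    eeg_n = normalize_tensor(eeg)
    return rank_sweep(meg_n.tensor, eeg_n.tensor, ranks, options)


def group_summary(sessions) -> pd.DataFrame:
    """Long-format group table over decomposed sessions.

    ``sessions`` is an iterable of ``(session_id, SessionConfig, CoupledResult,
    summaries_dict)``.  One row per modality and component, carrying the
    normalized obtained frequency, recruitment label, weight, reliability and
    residual.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("need at least one session")
    rows = []
    for session_id, cfg, result, summaries in sessions:
        residuals = {0: result.residuals[0], 1: result.residuals[1]}
        for mod_idx, (modality, comps) in enumerate(summaries.items()):
            for comp in comps:
                rows.append({
                    "session": session_id,
                    "modality": modality,
                    "component": comp.component,
                    "f_s_fraction": cfg.f_s_fraction,
                    "obtained_frequency_hz": comp.obtained_frequency_hz,
                    "normalized_frequency": comp.normalized_frequency,
                    "recruitment": comp.recruitment,
                    "weight": comp.weight,
                    "reliability": result.reliability,
                    "e_rec": residuals[mod_idx],
                })
    return pd.DataFrame(rows)
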