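"""Filtering and re-referencing.

Two filter branches are used downstream: the resting branch (0.53-120 Hz
band-pass with a 60 Hz notch) and the event-related branch (0.1-30 Hz).
Filters are 4th-order Butterworth band-pass plus a Q = 30 IIR notch,
applied forward-backward (zero phase) with reflect padding so component
latencies are not shifted and onset transients do not leak into 5-minute
records.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import signal

from .core import EEGRecording

REST_FILTER: "FilterSpec"
ERP_FILTER: "FilterSpec"


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float
    high_hz: float
    notch_hz: float | None = 60.0
    order: int = 4
    notch_q: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.notch_hz is not None and not (
            self.low_hz < self.notch_hz < self.high_hz
        ):
            raise ValueError("notch frequency must lie inside the passband")


REST_FILTER = FilterSpec(low_hz=0.53, high_hz=120.0, notch_hz=60.0)
ERP_FILTER = FilterSpec(low_hz=0.1, high_hz=30.0, notch_hz=None)


def bandpass_notch(rec: EEGRecording, spec: FilterSpec) -> EEGRecording:
    """Zero-phase Butterworth band-pass (+ optional notch) on every channel."""
    nyq = rec.rate / 2.0
    if spec.high_hz >= nyq:
        raise ValueError(
            f"high edge {spec.high_hz} Hz at or above Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                        btype="bandpass", fs=rec.rate, output="sos")
    padlen = min(rec.n_samples - 1, 3 * 2 * spec.order * 10)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1, padtype="even",
                             padlen=padlen)
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.rate)
        out = signal.filtfilt(b, a, out, axis=-1, padtype="even",
                              padlen=min(out.shape[-1] - 1, 300))
    return rec.copy_with(out)


def rereference(rec: EEGRecording, scheme: str = "linked-ear") -> EEGRecording:
    """Re-reference a recording.

    ``linked-ear`` is the identity for data generated against that
    reference; ``common-average`` subtracts the instantaneous channel mean,
    so output columns sum to zero.
    """
    if scheme == "linked-ear":
        return rec.copy_with(rec.data.copy())
    if scheme == "common-average":
        return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))
    raise ValueError(f"unknown reference scheme: {scheme!r}")
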