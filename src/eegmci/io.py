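"""Readers and writers for the on-disk formats.

EDF is the canonical on-disk EEG format (a minimal 16-bit writer lives
here; reading goes through MNE, which doubles as an independent check of
the writer).  BrainVision triplets (.vhdr/.vmrk/.eeg, IEEE float32) are
written for cue-marked task sessions and read back through MNE.  Subject
and trial tables travel as TSV, configurations as YAML.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHANNELS_1020, EEGRecording, Montage

#: cue-condition <-> BrainVision stimulus marker code
CONDITION_MARKERS = {"congruent": "S  1", "incongruent": "S  2",
                     "no_response": "S  3"}
_MARKER_CONDITIONS = {v.strip(): k for k, v in CONDITION_MARKERS.items()}


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _edf_num(value: float, width: int) -> bytes:
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.3g}", f"{value:.1e}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path, rec: EEGRecording, patient: str = "X",
              recording_id: str = "synthetic") -> Path:
    """Write a recording as EDF (16-bit, 1-s records, physical unit uV).

    The last record is zero-padded when the duration is not an integer
    number of seconds.
    """
    path = Path(path)
    rate = int(round(rec.rate))
    data = rec.data
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / rate))
    pad = n_rec * rate - n_samp
    if pad:
        data = np.concatenate([data, np.zeros((n_ch, pad))], axis=1)
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    # round through the 8-char header representation so the scale used for
    # encoding equals the one a reader will parse
    phys_max = np.array([float(_edf_num(v, 8).decode()) for v in phys_max])
    dig_max = 32767
    header = b"".join([
        _edf_field(0, 8), _edf_field(patient, 80), _edf_field(recording_id, 80),
        _edf_field("01.01.00", 8), _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8), _edf_field("", 44),
        _edf_field(n_rec, 8), _edf_num(1, 8), _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(c, 16) for c in rec.montage.channel_names),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_num(-phys_max[c], 8) for c in range(n_ch)),
        b"".join(_edf_num(phys_max[c], 8) for c in range(n_ch)),
        # symmetric digital range so the affine decode has zero offset
        b"".join(_edf_field(-dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(rate, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    scale = phys_max / dig_max
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            chunk = data[:, r * rate:(r + 1) * rate]
            digital = np.round(chunk / scale[:, None]).astype("<i2")
            fh.write(digital.tobytes())
    return path


def write_brainvision(stem, rec: EEGRecording,
                      events: pd.DataFrame | None = None) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, float32 multiplexed).

    ``events`` (columns ``sample``, ``condition``) become stimulus markers.
    Returns the .vhdr path.
    """
    stem = Path(stem)
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = rec.n_channels
    with open(vhdr, "w", encoding="utf-8") as fh:
        fh.write("BrainVision Data Exchange Header File Version 1.0\n\n")
        fh.write("[Common Infos]\nCodepage=UTF-8\n")
        fh.write(f"DataFile={eeg.name}\nMarkerFile={vmrk.name}\n")
        fh.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={n_ch}\n")
        fh.write(f"SamplingInterval={1e6 / rec.rate:.6f}\n\n")
        fh.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        fh.write("[Channel Infos]\n")
        for i, name in enumerate(rec.montage.channel_names, start=1):
            fh.write(f"Ch{i}={name},,1,µV\n")
    with open(vmrk, "w", encoding="ascii") as fh:
        fh.write("BrainVision Data Exchange Marker File Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={eeg.name}\n\n[Marker Infos]\n")
        fh.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        if events is not None:
            for j, (_, ev) in enumerate(events.iterrows(), start=2):
                code = CONDITION_MARKERS.get(str(ev["condition"]), "S 99")
                fh.write(f"Mk{j}=Stimulus,{code},{int(ev['sample']) + 1},1,0\n")
    rec.data.astype("<f4").T.tofile(eeg)
    return vhdr


def read_eeg(path) -> EEGRecording:
    """Read EDF or BrainVision EEG into the canonical recording object.

    Channels are mapped onto the 19-name 10-20 set (an error lists any
    absent electrode), amplitudes are normalized to uV, and stimulus
    annotations become the recording's event table.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format: {path.suffix!r}")
    have = {ch.strip(): i for i, ch in enumerate(raw.ch_names)}
    missing = [c for c in CHANNELS_1020 if c not in have]
    if missing:
        raise ValueError(f"recording is missing 10-20 channels: {missing}")
    idx = [have[c] for c in CHANNELS_1020]
    data_uv = raw.get_data()[idx] * 1e6
    events = None
    if len(raw.annotations):
        rows = []
        for ann in raw.annotations:
            desc = ann["description"].split("/")[-1].strip()
            cond = _MARKER_CONDITIONS.get(desc)
            if cond is not None:
                rows.append({"sample": int(round(ann["onset"] * raw.info["sfreq"])),
                             "condition": cond})
        if rows:
            events = pd.DataFrame(rows)
    return EEGRecording(data=data_uv, rate=float(raw.info["sfreq"]),
                        montage=Montage.standard_1020(), events=events)


def write_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
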