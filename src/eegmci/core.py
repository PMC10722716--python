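"""Core domain objects shared by every stage of the pipeline.

The recording montage is the 19-electrode international 10-20 set used by
portable dry-electrode systems (Fp1 ... Pz), placed at ideal angular
positions on a unit sphere.  All signal amplitudes are carried in microvolts
and sampling rates in samples per second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    import pandas as pd

#: canonical 10-20 channel order (old nomenclature T3/T4/T5/T6, as used by
#: 19-channel clinical systems)
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: left/right mirror pairs of the 10-20 set (midline channels map to themselves)
MIRROR_PAIRS = {
    "Fp1": "Fp2", "Fp2": "Fp1", "F3": "F4", "F4": "F3", "C3": "C4",
    "C4": "C3", "P3": "P4", "P4": "P3", "O1": "O2", "O2": "O1",
    "F7": "F8", "F8": "F7", "T3": "T4", "T4": "T3", "T5": "T6",
    "T6": "T5", "Fz": "Fz", "Cz": "Cz", "Pz": "Pz",
}


def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from inclination (angle from vertex Cz) and azimuth.

    Azimuth is measured in the axial plane from the nasion direction (+y),
    positive toward the right ear (+x).  z points up through Cz.
    """
    th = np.deg2rad(inclination_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def _ideal_1020_positions() -> dict[str, np.ndarray]:
    """Ideal 10-20 electrode placements on the unit sphere.

    The circumferential ring (Fp1/2, F7/8, T3/4, T5/6, O1/2) sits at 72 deg
    inclination; midline Fz/Pz at 36 deg; C3/C4 at 36 deg on the coronal
    arc.  F3/F4 and P3/P4 are the great-circle midpoints of (Fz, F7/F8) and
    (Pz, T5/T6), which is the geometric reading of the 10-20 construction.
    """
    pos = {
        "Cz": _sph(0, 0),
        "Fz": _sph(36, 0), "Pz": _sph(36, 180),
        "C3": _sph(36, -90), "C4": _sph(36, 90),
        "Fp1": _sph(72, -18), "Fp2": _sph(72, 18),
        "F7": _sph(72, -54), "F8": _sph(72, 54),
        "T3": _sph(72, -90), "T4": _sph(72, 90),
        "T5": _sph(72, -126), "T6": _sph(72, 126),
        "O1": _sph(72, -162), "O2": _sph(72, 162),
    }
    for mid, lat, name in (("Fz", "F7", "F3"), ("Fz", "F8", "F4"),
                           ("Pz", "T5", "P3"), ("Pz", "T6", "P4")):
        m = pos[mid] + pos[lat]
        pos[name] = m / np.linalg.norm(m)
    return pos


@dataclass(frozen=True)
class Montage:
    """Electrode set: ordered channel names and unit-sphere positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), on the unit sphere
    reference: str = "linked-ear"

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, float)
        if pos.shape != (len(names), 3):
            raise ValueError(f"positions shape {pos.shape} != ({len(names)}, 3)")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, 1.0, atol=1e-9):
            raise ValueError("electrode positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    @classmethod
    def standard_1020(cls, reference: str = "linked-ear") -> "Montage":
        """The default 19-channel 10-20 montage."""
        pos = _ideal_1020_positions()
        return cls(
            channel_names=CHANNELS_1020,
            positions=np.array([pos[c] for c in CHANNELS_1020]),
            reference=reference,
        )


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), uV
    rate: float  # Hz
    montage: Montage
    events: "pd.DataFrame | None" = None  # optional cue table (sample, condition)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} rows for {self.montage.n_channels} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        ev = None if self.events is None else self.events.copy()
        return EEGRecording(data=data, rate=self.rate, montage=self.montage, events=ev)


#: canonical analysis bands, Hz
DEFAULT_BANDS = (
    ("delta", 2.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 60.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands (shared edges allowed)."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        edges = [(lo, hi) for _, lo, hi in self.bands]
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError(f"band edges not ascending: {lo}..{hi}")
        for (_, hi_prev), (lo, _) in zip(edges, edges[1:]):
            if lo < hi_prev:
                raise ValueError("bands overlap")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    @property
    def edges(self) -> np.ndarray:
        return np.array([(lo, hi) for _, lo, hi in self.bands])
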