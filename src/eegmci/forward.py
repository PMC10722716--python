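"""Spherical head model and analytic lead field.

The conductor is three concentric spheres (brain, skull, scalp) with
conductivities in the classic 1 : 1/80 : 1 ratio.  Sources are current
dipoles with fixed radial orientation on a grid strictly inside the brain
sphere.  The scalp potential of a radial dipole is computed from the
Legendre series solution of the layered Poisson problem: for each harmonic
degree n the radial profile in layer j is ``A_j r^n + B_j r^-(n+1)``, with
the dipole's primary field entering the innermost layer, potential and
radial current continuous at the interfaces, and zero radial current at the
scalp surface.  This gives per-degree scalp coefficients c_n; the potential
at an electrode is ``sum_n c_n(b) P_n(cos gamma)`` with gamma the angle
between electrode and source.

Note a radial dipole does *not* vanish as it approaches the centre (the
n = 1 term survives), but the radial direction is undefined exactly at the
origin, so sources there are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre

from .core import Montage


@dataclass(frozen=True)
class HeadModel:
    """Three-shell spherical conductor (radii in arbitrary length units)."""

    radii: tuple[float, float, float] = (0.87, 0.92, 1.0)  # brain, skull, scalp
    conductivities: tuple[float, float, float] = (1.0, 1.0 / 80.0, 1.0)

    def __post_init__(self) -> None:
        r1, r2, r3 = self.radii
        if not 0 < r1 < r2 < r3:
            raise ValueError("radii must be strictly increasing and positive")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")


@dataclass(frozen=True)
class SourceSpace:
    """Source grid: unique 3-D points strictly inside the brain sphere."""

    voxel_coords: np.ndarray  # (n_voxels, 3)
    spacing_mm: float = 5.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.voxel_coords, float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise ValueError("voxel_coords must be (n >= 2, 3)")
        if len(np.unique(coords.round(12), axis=0)) != len(coords):
            raise ValueError("voxel coordinates must be unique")
        object.__setattr__(self, "voxel_coords", coords)

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]

    @classmethod
    def regular_grid(cls, n_target: int = 200, head: HeadModel | None = None,
                     max_radius_frac: float = 0.85) -> "SourceSpace":
        """Cubic grid clipped to a ball of ``max_radius_frac x brain radius``.

        ``n_target`` controls resolution; the realized count is the nearest
        grid that fits (the reference full-resolution atlas has 6239 voxels
        at 5-mm spacing; desk-scale analyses use a few hundred).
        """
        head = head or HeadModel()
        r_max = max_radius_frac * head.radii[0]
        # choose grid step so that the ball holds about n_target points
        step = (4.0 / 3.0 * np.pi * r_max**3 / max(n_target, 2)) ** (1.0 / 3.0)
        ax = np.arange(-r_max, r_max + step / 2, step)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        r = np.linalg.norm(pts, axis=1)
        pts = pts[(r <= r_max) & (r > 1e-9)]
        return cls(voxel_coords=pts, spacing_mm=step * 100.0)


def _scalp_coefficients(b_over: np.ndarray, head: HeadModel, n_terms: int) -> np.ndarray:
    """Per-degree scalp coefficients c_n for radial unit dipoles.

    ``b_over``: source radii (same units as head radii).  Returns array
    (n_sources, n_terms) with c[:, n-1] the coefficient multiplying
    P_n(cos gamma) in the scalp potential.
    """
    r1, r2, r3 = head.radii
    s1, s2, s3 = head.conductivities
    ns = np.arange(1, n_terms + 1, dtype=float)
    out = np.empty((len(b_over), n_terms))
    # Solve, per degree n, the 5x5 linear system for (A1, A2, B2, A3, B3);
    # the source term fixes B1 = n b^(n-1) / (4 pi s1).
    for j, n in enumerate(ns):
        M = np.array([
            # continuity of V at r1:  A1 r1^n + B1 r1^-(n+1) = A2 r1^n + B2 r1^-(n+1)
            [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0],
            # continuity of s dV/dr at r1
            [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
             s2 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0],
            # continuity of V at r2
            [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))],
            # continuity of s dV/dr at r2
            [0.0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
             -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)],
            # zero radial current at the outer surface r3
            [0.0, 0.0, 0.0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)],
        ])
        rhs_template = np.array([
            -(r1 ** -(n + 1)),
            s1 * (n + 1) * r1 ** -(n + 2),
            0.0, 0.0, 0.0,
        ])
        Minv = np.linalg.inv(M)
        for i, b in enumerate(b_over):
            B1 = n * b ** (n - 1) / (4.0 * np.pi * s1)
            sol = Minv @ (rhs_template * B1)
            A3, B3 = sol[3], sol[4]
            out[i, j] = A3 * r3**n + B3 * r3 ** -(n + 1)
    return out


@dataclass(frozen=True)
class LeadField:
    """Scalp potential of unit radial dipoles: (n_channels, n_voxels).

    Columns are average-referenced, matching the reference-free character
    of the inverse problem.
    """

    matrix: np.ndarray
    montage: Montage
    source_space: SourceSpace
    head_model: HeadModel

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]


def build_forward(montage: Montage, source_space: SourceSpace,
                  head_model: HeadModel | None = None,
                  n_terms: int = 60) -> LeadField:
    """Analytic three-sphere lead field for radial dipoles.

    Electrodes sit on the outer sphere (unit-sphere montage positions scaled
    to the scalp radius); sources must be strictly inside the brain sphere
    and off the exact origin (radial orientation undefined there).
    """
    head = head_model or HeadModel()
    coords = source_space.voxel_coords
    radii = np.linalg.norm(coords, axis=1)
    if np.any(radii >= head.radii[0]):
        bad = int(np.argmax(radii >= head.radii[0]))
        raise ValueError(
            f"source {bad} at radius {radii[bad]:.4f} is outside the brain "
            f"sphere (radius {head.radii[0]})"
        )
    if np.any(radii < 1e-9):
        raise ValueError("radial orientation undefined at the origin; "
                         "place sources strictly off-centre")
    elec = montage.positions * head.radii[2]
    # cos(gamma) between each electrode and each source direction
    cosg = (montage.positions @ (coords / radii[:, None]).T)
    cosg = np.clip(cosg, -1.0, 1.0)
    coef = _scalp_coefficients(radii, head, n_terms)  # (Nv, n_terms)
    # evaluate sum_n c_n P_n(cos gamma) via a Legendre series per source
    K = np.empty((montage.n_channels, source_space.n_voxels))
    for v in range(source_space.n_voxels):
        c = np.concatenate([[0.0], coef[v]])  # degree-0 term absent
        K[:, v] = legendre.legval(cosg[:, v], c)
    K -= K.mean(axis=0, keepdims=True)  # average reference
    return LeadField(matrix=K, montage=montage, source_space=source_space,
                     head_model=head)
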