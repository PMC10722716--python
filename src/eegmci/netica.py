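"""Group ICA of spectrocortical images and network-activity comparison.

Subjects' band-power images are flattened band-major into a
(subjects x n_bands*n_voxels) matrix.  The decomposition is spatial:
after centering across subjects, FastICA (tanh contrast) is run on the
whitened transpose, so the *maps* are maximally independent over the
voxel-band dimension and each subject's *loadings* ("network activities")
are the mixing coefficients.  Components are ordered by total power
(descending energy of loading x map), signs fixed so each map's
largest-magnitude weight is positive.  Once fitted, the fixed maps
produce loadings for any new subject by least squares against the
centred image, which is exact for training subjects.

Group contrast on loadings: a two-sample t statistic (MCI - HC) with a
one-tailed label-permutation p-value for the alternative "MCI lower".
A permutation null is used because the published t/p pairing does not
match a parametric two-sample null at the published group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import BandScheme
from .inverse import SpectroCorticalImage

DEFAULT_K = 15


@dataclass
class GroupDataMatrix:
    """(n_subjects x n_bands*n_voxels) band-major stack of images."""

    matrix: np.ndarray
    subject_ids: list[str]
    bands: BandScheme
    n_voxels: int

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def column_of(self, band: int | str, voxel: int) -> int:
        """Column index of (band, voxel) under band-major order."""
        b = self.bands.names.index(band) if isinstance(band, str) else band
        return b * self.n_voxels + voxel

    def unflatten(self, row: np.ndarray) -> np.ndarray:
        """Row vector back to an (n_voxels, n_bands) image."""
        return row.reshape(self.bands.n_bands, self.n_voxels).T


def build_group_matrix(images: list[SpectroCorticalImage]) -> GroupDataMatrix:
    """Stack subject images; every image must share (n_voxels, n_bands)."""
    if not images:
        raise ValueError("no images supplied")
    ref = images[0]
    rows = []
    for img in images:
        if img.values.shape != ref.values.shape:
            raise ValueError(
                f"subject {img.subject_id!r} image shape {img.values.shape} "
                f"differs from {ref.values.shape}"
            )
        rows.append(img.values.T.reshape(-1))  # band-major
    return GroupDataMatrix(matrix=np.vstack(rows),
                           subject_ids=[im.subject_id for im in images],
                           bands=ref.bands, n_voxels=ref.n_voxels)


@dataclass
class ICADecomposition:
    """K spectrocortical maps + per-subject loadings (network activities)."""

    maps: np.ndarray          # (K, n_bands*n_voxels)
    loadings: np.ndarray      # (n_subjects, K)
    mean_image: np.ndarray    # (n_bands*n_voxels,)
    subject_ids: list[str]
    bands: BandScheme
    n_voxels: int
    seed: int
    artifact_flags: np.ndarray = field(default=None)  # bool per component

    def __post_init__(self) -> None:
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.k, bool)

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def total_power(self) -> np.ndarray:
        """Per-component energy: sum over subjects of (loading x map)^2."""
        return (self.loadings**2).sum(axis=0) * (self.maps**2).sum(axis=1)

    def reconstruct(self) -> np.ndarray:
        return self.loadings @ self.maps + self.mean_image


def fit_group_ica(gm: GroupDataMatrix, k: int = DEFAULT_K, seed: int = 0,
                  max_retries: int = 5) -> ICADecomposition:
    """Spatial FastICA of the group matrix.

    Deterministic given ``seed``; on non-convergence the rotation is
    retried with derived seeds up to ``max_retries`` times, then raises.
    """
    X = gm.matrix
    n, p = X.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n_subjects={n}, n_features={p})")
    mean_image = X.mean(axis=0)
    Xc = X - mean_image
    # economy SVD; whitened feature-space samples are sqrt(p) * V_k
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[min(k, len(S)) - 1] <= S[0] * 1e-12:
        warnings.warn("data rank below k; trailing components are noise",
                      stacklevel=2)
    Z = np.sqrt(p) * Vt[:k].T  # (p, k), identity covariance
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rs = int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0])
        rs %= 2**32 - 1
        ica = FastICA(n_components=k, whiten=False, fun="logcosh",
                      random_state=int(rs), max_iter=500, tol=1e-6)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                Sica = ica.fit_transform(Z)  # (p, k) independent maps
            except Exception as err:  # pragma: no cover
                last_err = err
                continue
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            last_err = RuntimeError("FastICA did not converge")
            continue
        break
    else:
        raise RuntimeError(f"FastICA failed after {max_retries} seeds: {last_err}")
    W = ica.components_  # (k, k) rotation: Sica = Z @ W.T
    maps = Sica.T  # (k, p)
    # loadings solve Xc ~= A maps: A = U_k S_k W^T / sqrt(p)
    loadings = (U[:, :k] * S[:k]) @ W.T / np.sqrt(p)
    # order by total power, descending
    power = (loadings**2).sum(axis=0) * (maps**2).sum(axis=1)
    order = np.argsort(power)[::-1]
    maps, loadings = maps[order], loadings[:, order]
    # sign convention: largest-|weight| entry of each map positive
    signs = np.sign(maps[np.arange(k), np.argmax(np.abs(maps), axis=1)])
    signs[signs == 0] = 1.0
    maps *= signs[:, None]
    loadings *= signs[None, :]
    return ICADecomposition(maps=maps, loadings=loadings, mean_image=mean_image,
                            subject_ids=list(gm.subject_ids), bands=gm.bands,
                            n_voxels=gm.n_voxels, seed=seed)


def project_subject(dec: ICADecomposition, image: SpectroCorticalImage) -> np.ndarray:
    """Loadings of a (possibly new) subject on the fixed maps.

    Least-squares projection of the centred band-major vector onto the
    maps; training subjects recover their training loadings exactly and
    the cohort mean image projects to zero.
    """
    expect = (dec.n_voxels, dec.bands.n_bands)
    if image.values.shape != expect:
        raise ValueError(f"image shape {image.values.shape} != {expect}")
    x = image.values.T.reshape(-1) - dec.mean_image
    sol, *_ = np.linalg.lstsq(dec.maps.T, x, rcond=None)
    return sol


@dataclass
class NetworkComparison:
    component: int
    t: float
    p_one_tailed: float
    mean_hc: float
    sd_hc: float
    mean_mci: float
    sd_mci: float


def _t_stat(x: np.ndarray, labels_mci: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (MCI - HC); vectorized over columns."""
    x = np.atleast_2d(x)
    n1 = labels_mci.sum()
    n0 = len(labels_mci) - n1
    m1 = x[:, labels_mci].mean(axis=1)
    m0 = x[:, ~labels_mci].mean(axis=1)
    v1 = x[:, labels_mci].var(axis=1, ddof=1)
    v0 = x[:, ~labels_mci].var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    denom = sp * np.sqrt(1.0 / n1 + 1.0 / n0)
    denom[denom == 0] = np.inf
    return (m1 - m0) / denom


def compare_networks(dec: ICADecomposition, groups, n_perm: int = 5000,
                     seed: int = 0, alternative: str = "less",
                     ) -> list[NetworkComparison]:
    """One-tailed permutation test per physiological component.

    ``groups`` holds "HC"/"MCI" per subject; artifact-flagged components
    are excluded.  The permutation p is
    ``(1 + #{t_perm <= t_obs}) / (n_perm + 1)`` for the default
    alternative "MCI < HC" (``greater`` flips the tail).
    """
    groups = np.asarray(groups)
    is_mci = groups == "MCI"
    if is_mci.sum() < 2 or (~is_mci).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    keep = np.where(~dec.artifact_flags)[0]
    L = dec.loadings[:, keep].T  # (n_keep, n_subjects)
    t_obs = _t_stat(L, is_mci)
    rng = np.random.default_rng(seed)
    count = np.zeros(len(keep))
    for _ in range(n_perm):
        perm = rng.permutation(is_mci)
        t_perm = _t_stat(L, perm)
        if alternative == "less":
            count += t_perm <= t_obs
        else:
            count += t_perm >= t_obs
    p = (1.0 + count) / (n_perm + 1.0)
    out = []
    for j, comp in enumerate(keep):
        out.append(NetworkComparison(
            component=int(comp), t=float(t_obs[j]), p_one_tailed=float(p[j]),
            mean_hc=float(L[j, ~is_mci].mean()), sd_hc=float(L[j, ~is_mci].std(ddof=1)),
            mean_mci=float(L[j, is_mci].mean()), sd_mci=float(L[j, is_mci].std(ddof=1)),
        ))
    return out


def match_components(dec: ICADecomposition, true_maps: np.ndarray) -> pd.DataFrame:
    """Greedy |correlation| assignment of fitted maps to planted maps.

    ``true_maps`` is (K_true, n_bands, n_voxels) or already flat.  Returns
    one row per planted map: fitted component index, correlation, sign.
    """
    flat = true_maps.reshape(true_maps.shape[0], -1)
    C = np.corrcoef(np.vstack([flat, dec.maps]))[:len(flat), len(flat):]
    rows = []
    used: set[int] = set()
    for ti in np.argsort(-np.max(np.abs(C), axis=1)):
        order = np.argsort(-np.abs(C[ti]))
        fi = next(int(j) for j in order if int(j) not in used)
        used.add(fi)
        rows.append({"true_map": int(ti), "component": fi,
                     "correlation": float(C[ti, fi]),
                     "sign": float(np.sign(C[ti, fi]) or 1.0)})
    return pd.DataFrame(rows).sort_values("true_map").reset_index(drop=True)
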