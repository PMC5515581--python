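"""Spherule geometry: radius and volume, inter-filament spacing, size classes.

Volumes follow the widest-circumference convention: the reported radius is
half the maximum caliper diameter of the vesicle boundary and the volume is
the sphere formula on that radius.  Size classes are formalized as BIC-
selected Gaussian mixtures fit by expectation-maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from .volumes import DensityVolume

__all__ = [
    "SpheruleMeasurement",
    "VolumeMixtureModel",
    "measure_spherule",
    "interfilament_spacing",
    "fit_volume_mixture",
    "summarize_volumes",
]


@dataclass
class SpheruleMeasurement:
    """Center, widest-circumference radius, and spherical volume of one vesicle."""

    center_nm: np.ndarray
    radius_nm: float
    volume_nm3: float

    @staticmethod
    def from_radius(center_nm, radius_nm: float) -> "SpheruleMeasurement":
        return SpheruleMeasurement(
            center_nm=np.asarray(center_nm, dtype=float),
            radius_nm=float(radius_nm),
            volume_nm3=sphere_volume(radius_nm),
        )

    @property
    def implied_radius_nm(self) -> float:
        return float((3.0 * self.volume_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def sphere_volume(radius_nm: float) -> float:
    """(4/3) pi r^3 — the widest-circumference volume convention."""
    return float(4.0 / 3.0 * np.pi * float(radius_nm) ** 3)


def measure_spherule(
    source,
    center_guess_nm=None,
    voxel_size_nm: float | None = None,
    search_radius_nm: float = 60.0,
) -> SpheruleMeasurement:
    """Measure a spherule from a boundary point cloud or a density map.

    ``source`` is either an (N, 3) array of boundary points in nm (z,y,x) —
    e.g. synthetic ground truth — or a :class:`DensityVolume`, in which case
    the membrane shell is segmented by Otsu threshold within
    ``search_radius_nm`` of ``center_guess_nm``.  The radius is half the
    maximum caliper diameter of the boundary ("widest circumference").
    """
    if isinstance(source, DensityVolume):
        if center_guess_nm is None:
            center_guess_nm = (np.array(source.data.shape) - 1) / 2.0 * source.voxel_size_nm
        pts = _boundary_points_from_map(source, np.asarray(center_guess_nm, float), search_radius_nm)
    else:
        pts = np.asarray(source, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("boundary must be an (N, 3) point array in nm")
    if len(pts) < 4:
        raise ValueError("no closed boundary found: fewer than 4 boundary points")
    center, radius = _caliper_radius(pts)
    return SpheruleMeasurement(center_nm=center, radius_nm=radius, volume_nm3=sphere_volume(radius))


def _caliper_radius(pts: np.ndarray, n_axes: int = 64, cap_deg: float = 16.0):
    """Half the maximum caliper diameter of a boundary point cloud.

    The diameter along an axis is the sum of the mean point radii inside the
    two antipodal caps about that axis — averaging within a cap keeps the
    caliper from riding on the outermost noise excursions of the boundary.
    """
    center = pts.mean(axis=0)
    rel = pts - center
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0):
        rel = rel[r > 0]
        r = r[r > 0]
    units = rel / r[:, None]
    k = np.arange(n_axes)
    z = 1.0 - 2.0 * (k + 0.5) / n_axes
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    axes = np.column_stack(
        [np.sqrt(1 - z**2) * np.cos(phi), np.sqrt(1 - z**2) * np.sin(phi), z]
    )
    cos_cap = np.cos(np.deg2rad(cap_deg))
    best = 0.0
    dots = units[:, ::-1] @ axes.T  # unit vectors are (z,y,x); axes are xyz
    for j in range(n_axes):
        plus = r[dots[:, j] >= cos_cap]
        minus = r[dots[:, j] <= -cos_cap]
        if len(plus) and len(minus):
            best = max(best, float(plus.mean() + minus.mean()))
    if best == 0.0:
        # boundary too sparse for cap averaging: fall back to the hull caliper
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
        d2 = np.sum((hp[:, None, :] - hp[None, :, :]) ** 2, axis=-1)
        best = float(np.sqrt(d2.max()))
    return center, best / 2.0


def _boundary_points_from_map(
    vol: DensityVolume, center_nm, search_radius_nm, exclude_cone_deg: float = 45.0, n_dirs: int = 500
) -> np.ndarray:
    """Membrane midline points: radial density peaks along sampled directions.

    Directions within ``exclude_cone_deg`` of +z are skipped so the neck and
    the planar outer membrane above it do not contaminate the vesicle
    boundary.  Peaks must clear the Otsu threshold of the search region.
    """
    from scipy import ndimage

    voxel = vol.voxel_size_nm
    center_vox = np.asarray(center_nm, dtype=float) / voxel
    # Fibonacci directions outside the neck cone (xyz components)
    k = np.arange(n_dirs)
    z = 1.0 - 2.0 * (k + 0.5) / n_dirs
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs = dirs[z < np.cos(np.deg2rad(exclude_cone_deg))]

    radii = np.arange(2.0, search_radius_nm, voxel / 2.0)
    # sample all (direction, radius) pairs at once
    pts_xyz = dirs[:, None, :] * radii[None, :, None]  # (nd, nr, 3)
    coords = pts_xyz[..., ::-1].reshape(-1, 3) / voxel + center_vox  # to (z,y,x) vox
    vals = ndimage.map_coordinates(vol.data, coords.T, order=1, mode="constant", cval=0.0)
    vals = vals.reshape(len(dirs), len(radii))
    if np.all(vals == vals.flat[0]):
        raise ValueError("no closed boundary found near the given center")
    thr = threshold_otsu(vals.ravel())
    peak_idx = np.argmax(vals, axis=1)
    keep = vals[np.arange(len(dirs)), peak_idx] >= thr
    if keep.sum() < 4:
        raise ValueError("no closed boundary found: too few radial membrane peaks")
    boundary_xyz = dirs[keep] * radii[peak_idx[keep], None]
    boundary_zyx = boundary_xyz[:, ::-1] + np.asarray(center_nm, dtype=float)
    return boundary_zyx


def interfilament_spacing(
    paths,
    sample_step_nm: float = 2.0,
    exclusion_arc_nm: float = 62.0,
    min_pairs: int = 10,
) -> float:
    """Mean nearest-neighbor center-to-center distance between filament strands.

    ``paths`` is a single (N, 3) polyline in nm or a list of polylines (e.g.
    one per cylinder in a lattice).  For each sampled cross-section the
    nearest neighbor is sought among points of other strands or of the same
    strand farther than ``exclusion_arc_nm`` along the contour — pairs closer
    in arc than one persistence length are the same locally straight segment,
    not a packing neighbor.
    """
    if isinstance(paths, np.ndarray) and paths.ndim == 2:
        paths = [paths]
    pts_all, strand_ids, arcs = [], [], []
    for si, path in enumerate(paths):
        path = np.asarray(path, dtype=float)
        if path.ndim != 2 or path.shape[1] != 3 or len(path) < 2:
            raise ValueError("each path must be an (N>=2, 3) polyline in nm")
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        # resample at uniform arc step so the estimate is not density-weighted
        total = arc[-1]
        if total <= 0:
            continue
        n_samp = max(2, int(total / sample_step_nm) + 1)
        t = np.linspace(0.0, total, n_samp)
        res = np.column_stack([np.interp(t, arc, path[:, k]) for k in range(3)])
        pts_all.append(res)
        strand_ids.append(np.full(len(res), si))
        arcs.append(t)
    pts = np.concatenate(pts_all)
    sid = np.concatenate(strand_ids)
    arc = np.concatenate(arcs)
    if len(pts) < min_pairs:
        raise ValueError(f"too few sampled points ({len(pts)}) for a spacing estimate")

    tree = cKDTree(pts)
    k = min(len(pts), 64)
    dists, idx = tree.query(pts, k=k)
    out = []
    for i in range(len(pts)):
        for d, j in zip(dists[i][1:], idx[i][1:]):
            j = int(j)
            if sid[j] != sid[i] or abs(arc[j] - arc[i]) > exclusion_arc_nm:
                out.append(d)
                break
    if len(out) < min_pairs:
        raise ValueError("too few measurable cross-section pairs")
    return float(np.mean(out))


@dataclass
class VolumeMixtureModel:
    """BIC-selected Gaussian mixture over spherule volumes (Results object).

    Means are sorted ascending; ``bic_by_k`` records the model-selection
    trace so the choice of k is auditable.
    """

    k: int
    means_nm3: np.ndarray
    sds_nm3: np.ndarray
    weights: np.ndarray
    bic: float
    n: int
    converged: bool
    bic_by_k: dict

    def summary(self) -> str:
        lines = [
            "Gaussian mixture over spherule volumes",
            f"  n = {self.n}, selected k = {self.k} (BIC {self.bic:.1f}), converged = {self.converged}",
            f"  {'component':>9} {'weight':>8} {'mean (nm^3)':>14} {'sd (nm^3)':>12}",
        ]
        for i in range(self.k):
            lines.append(
                f"  {i + 1:>9d} {self.weights[i]:>8.3f} {self.means_nm3[i]:>14.0f} {self.sds_nm3[i]:>12.0f}"
            )
        return "\n".join(lines)


def fit_volume_mixture(volumes, k_range=(1, 5), seed: int = 0, n_init: int = 5) -> VolumeMixtureModel:
    """EM fit of Gaussian mixtures for each k; lowest BIC wins.

    Deterministic under a fixed seed; non-convergence after the restart
    budget is flagged on the result rather than raised.
    """
    x = np.asarray(volumes, dtype=float).reshape(-1, 1)
    k_lo, k_hi = k_range
    if len(x) < 10 * k_hi:
        raise ValueError(f"need at least 10*k_max = {10 * k_hi} samples, got {len(x)}")
    best = None
    bic_by_k = {}
    for k in range(k_lo, k_hi + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            max_iter=500,
        ).fit(x)
        bic = float(gm.bic(x))
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    order = np.argsort(gm.means_.ravel())
    return VolumeMixtureModel(
        k=k,
        means_nm3=gm.means_.ravel()[order],
        sds_nm3=np.sqrt(gm.covariances_.reshape(k, -1)[:, 0])[order],
        weights=gm.weights_[order],
        bic=bic,
        n=len(x),
        converged=bool(gm.converged_),
        bic_by_k=bic_by_k,
    )


def summarize_volumes(volumes) -> pd.Series:
    """Descriptive statistics (n, mean, sd with n-1 denominator, min, max)."""
    x = np.asarray(volumes, dtype=float)
    if x.size == 0:
        raise ValueError("empty volume list")
    return pd.Series(
        {
            "n": int(x.size),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "min": float(x.min()),
            "max": float(x.max()),
        }
    )
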