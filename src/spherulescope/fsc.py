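"""Fourier shell correlation between independent half maps.

Resolution is reported at the conventional 0.5 and 0.143 thresholds as the
reciprocal of the frequency of the first downward crossing.  Shells are one
voxel wide in Fourier space (integer radii), the simplest auditable binning.
A soft cosine-edged spherical mask is applied by default and its use is
recorded on the curve, since masking is a known way to inflate FSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import DensityVolume

__all__ = ["FSCCurve", "compute_fsc", "resolution_at_threshold", "soft_spherical_mask"]


@dataclass
class FSCCurve:
    """Per-shell correlation between two half maps.

    ``shell_freq_inv_nm`` are shell-center spatial frequencies (1/nm), strictly
    increasing up to Nyquist; ``correlation`` lies in [-1, 1]; shells with no
    power are reported as 0 and flagged in ``zero_power_shells``.
    """

    shell_freq_inv_nm: np.ndarray
    correlation: np.ndarray
    n_voxels_per_shell: np.ndarray
    voxel_size_nm: float
    mask_applied: str = ""
    zero_power_shells: list = field(default_factory=list)

    def __len__(self):
        return len(self.shell_freq_inv_nm)


def soft_spherical_mask(shape, edge_vox: float = 3.0, radius_vox: float | None = None) -> np.ndarray:
    """Spherical mask with a cosine edge of ``edge_vox`` voxels."""
    center = (np.array(shape) - 1) / 2.0
    if radius_vox is None:
        radius_vox = min(shape) / 2.0 - edge_vox
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r = np.sqrt(((zz - center[0])) ** 2 + ((yy - center[1])) ** 2 + ((xx - center[2])) ** 2)
    mask = np.clip((radius_vox + edge_vox - r) / edge_vox, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * mask)).astype(np.float32)


def compute_fsc(
    half_a: DensityVolume,
    half_b: DensityVolume,
    mask: np.ndarray | str | None = "soft-sphere",
) -> FSCCurve:
    """Shell-wise normalized cross-correlation of two half maps.

    ``mask`` may be ``"soft-sphere"`` (default; cosine-edged, 3-voxel edge),
    ``None`` for no masking, or an explicit real-space array.  The applied
    mask is recorded on the returned curve.
    """
    if half_a.data.shape != half_b.data.shape:
        raise ValueError(
            f"half-map shapes differ: {half_a.data.shape} vs {half_b.data.shape}"
        )
    if not np.isclose(half_a.voxel_size_nm, half_b.voxel_size_nm):
        raise ValueError("half-map voxel sizes differ")
    a = half_a.data.astype(np.float64)
    b = half_b.data.astype(np.float64)
    mask_label = ""
    if isinstance(mask, str):
        if mask != "soft-sphere":
            raise ValueError(f"unknown mask name {mask!r}")
        m = soft_spherical_mask(a.shape)
        mask_label = "soft-sphere(edge=3vox)"
    elif mask is not None:
        m = np.asarray(mask, dtype=np.float64)
        mask_label = "user-supplied"
    else:
        m = None
    if m is not None:
        a = a * m
        b = b * m

    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    shape = a.shape
    grids = np.meshgrid(*[np.fft.fftfreq(n) * n for n in shape], indexing="ij")
    radius = np.sqrt(sum(g**2 for g in grids))
    nyq = min(shape) // 2
    shell_idx = np.round(radius).astype(int)

    corr, counts, zero_flags = [], [], []
    cross = fa * np.conj(fb)
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    flat_idx = shell_idx.ravel()
    num = np.bincount(flat_idx, weights=np.real(cross).ravel(), minlength=nyq + 1)
    da = np.bincount(flat_idx, weights=pa.ravel(), minlength=nyq + 1)
    db = np.bincount(flat_idx, weights=pb.ravel(), minlength=nyq + 1)
    nvox = np.bincount(flat_idx, minlength=nyq + 1)
    for s in range(1, nyq + 1):
        denom = np.sqrt(da[s] * db[s])
        if denom == 0:
            corr.append(0.0)
            zero_flags.append(s)
        else:
            corr.append(float(np.clip(num[s] / denom, -1.0, 1.0)))
        counts.append(int(nvox[s]))

    freqs = np.arange(1, nyq + 1) / (min(shape) * half_a.voxel_size_nm)
    return FSCCurve(
        shell_freq_inv_nm=freqs,
        correlation=np.asarray(corr),
        n_voxels_per_shell=np.asarray(counts),
        voxel_size_nm=half_a.voxel_size_nm,
        mask_applied=mask_label,
        zero_power_shells=zero_flags,
    )


def resolution_at_threshold(curve: FSCCurve, threshold: float) -> tuple[float, bool]:
    """Resolution (nm) at the first downward crossing of ``threshold``.

    Linearly interpolates the crossing frequency between shells.  If the
    curve never drops below the threshold the Nyquist-limited resolution is
    returned with the flag set.
    Returns ``(resolution_nm, nyquist_limited)``.
    """
    if len(curve) == 0:
        raise ValueError("empty FSC curve")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    c = np.asarray(curve.correlation, dtype=float)
    f = np.asarray(curve.shell_freq_inv_nm, dtype=float)
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return float(1.0 / f[-1]), True
    i = below[0]
    if i == 0:
        return float(1.0 / f[0]), False
    f0, f1 = f[i - 1], f[i]
    c0, c1 = c[i - 1], c[i]
    fc = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0)
    return float(1.0 / fc), False
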