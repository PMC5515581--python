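"""Cyclic symmetry detection from angular intensity profiles.

The density is sampled along circles about a chosen axis within an annular
band (by default the teeth ring, 15-20 nm radius, just above the membrane),
each azimuthal profile is Fourier transformed, and the per-component power is
averaged over particles.  A k-fold symmetric structure concentrates power in
rotational component k; the detector reports the most prominent component,
preferring the fundamental over its harmonics.  Component 0 (the mean) is
excluded, and component 1 is a quality metric for axis miscentring rather
than a symmetry candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import CrownSpec
from .volumes import DensityVolume, euler_to_matrix

__all__ = [
    "AngularPowerSpectrum",
    "angular_intensity_profile",
    "rotational_power_spectrum",
    "detect_symmetry_order",
    "crown_band_defaults",
]


@dataclass
class AngularPowerSpectrum:
    """Mean Fourier power per rotational component, averaged over profiles."""

    component: np.ndarray
    mean_power: np.ndarray
    n_profiles_averaged: int
    radius_band_nm: tuple
    height_band_nm: tuple

    def __post_init__(self):
        if np.any(self.mean_power < 0):
            raise ValueError("power must be non-negative")

    @property
    def miscentring_power(self) -> float:
        """Power at component 1 — elevated when the axis misses the center."""
        return float(self.mean_power[1]) if len(self.mean_power) > 1 else 0.0


def crown_band_defaults(spec: CrownSpec = CrownSpec()) -> tuple[tuple, tuple]:
    """(radius_band_nm, height_band_nm) spanning the teeth ring of a crown map.

    Heights are relative to the box center of a map rendered by
    ``make_crown_density`` (membrane surface at -turret_height/2).
    """
    r = spec.teeth_ring_diameter_nm / 2.0
    radius_band = (r - 2.5, r + 2.5)
    z_surf = -spec.turret_height_nm / 2.0
    height_band = (z_surf + spec.teeth_height_nm - 2.0, z_surf + spec.teeth_height_nm + 2.0)
    return radius_band, height_band


def angular_intensity_profile(
    vol: DensityVolume,
    radius_band_nm: tuple,
    height_band_nm: tuple,
    n_samples: int = 128,
    euler_zyz_deg=(0.0, 0.0, 0.0),
    center_vox=None,
    n_radial: int = 5,
    n_axial: int = 5,
) -> np.ndarray:
    """Mean density at each of ``n_samples`` azimuths over an annular band.

    The band is a set of circles of radii spanning ``radius_band_nm`` at
    heights spanning ``height_band_nm`` along the (possibly tilted) axis
    defined by ``euler_zyz_deg`` about ``center_vox``; values are interpolated
    trilinearly.
    """
    if n_samples < 4 or (n_samples & (n_samples - 1)) != 0:
        raise ValueError("n_samples must be a power of two >= 4")
    r_in, r_out = radius_band_nm
    if not r_in < r_out:
        raise ValueError("degenerate radius band (inner >= outer)")
    h_lo, h_hi = height_band_nm
    voxel = vol.voxel_size_nm
    shape = np.array(vol.data.shape)
    center = (shape - 1) / 2.0 if center_vox is None else np.asarray(center_vox, dtype=float)

    max_r_vox = r_out / voxel
    if np.any(center - max_r_vox < -0.5) or np.any(center + max_r_vox > shape - 0.5):
        raise ValueError("radius band extends outside the volume")

    R = euler_to_matrix(euler_zyz_deg)  # xyz
    theta = 2.0 * np.pi * np.arange(n_samples) / n_samples
    radii = np.linspace(r_in, r_out, n_radial)
    heights = np.linspace(h_lo, h_hi, n_axial)
    tt, rr, hh = np.meshgrid(theta, radii, heights, indexing="ij")
    # band points in the axis frame (xyz, nm)
    pts = np.stack(
        [rr * np.cos(tt), rr * np.sin(tt), hh], axis=-1
    ).reshape(-1, 3)
    pts_tomo = pts @ R.T  # rotate axis frame into the volume frame
    coords_vox = pts_tomo[:, ::-1] / voxel + center  # to (z,y,x) voxels
    vals = ndimage.map_coordinates(vol.data, coords_vox.T, order=1, mode="nearest")
    return vals.reshape(n_samples, -1).mean(axis=1)


def rotational_power_spectrum(profiles) -> "AngularPowerSpectrum | np.ndarray":
    """Average discrete Fourier power of mean-subtracted azimuthal profiles."""
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    if len(profiles) == 0:
        raise ValueError("no profiles supplied")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("profiles have ragged lengths")
    power = np.zeros(n // 2 + 1)
    for p in profiles:
        spec = np.fft.rfft(p - p.mean())
        power += np.abs(spec) ** 2 / n
    power /= len(profiles)
    return AngularPowerSpectrum(
        component=np.arange(n // 2 + 1),
        mean_power=power,
        n_profiles_averaged=len(profiles),
        radius_band_nm=(np.nan, np.nan),
        height_band_nm=(np.nan, np.nan),
    )


def detect_symmetry_order(
    spectrum: AngularPowerSpectrum,
    search_range: tuple = (2, 24),
    prominence_threshold: float = 2.0,
) -> tuple[int | None, float]:
    """Most prominent rotational component, or None if nothing stands out.

    Prominence is the candidate's power over the median power in the search
    range.  If both a component k and its harmonic 2k exceed the threshold,
    the fundamental k is reported (the physical subunit count).
    """
    lo, hi = search_range
    if lo < 2:
        raise ValueError("search range must start at component >= 2")
    hi = min(hi, len(spectrum.mean_power) - 1)
    comps = np.arange(lo, hi + 1)
    powers = spectrum.mean_power[lo : hi + 1]
    # floor the reference level so a near-empty spectrum (clean phantoms)
    # cannot make noise-level components look prominent
    med = max(float(np.median(powers)), 1e-3 * float(powers.max()), 1e-300)
    best = int(comps[np.argmax(powers)])
    prominence = float(spectrum.mean_power[best] / med)
    if prominence < prominence_threshold:
        return None, prominence
    # Fundamental-vs-harmonic tie-break: when the argmax is the harmonic of a
    # component that is itself prominent AND carries comparable power (at
    # least a third of the harmonic's), report the fundamental — the physical
    # subunit count.  A trace of power at k/2 must not demote a clean peak.
    if best % 2 == 0 and best // 2 >= lo:
        half = best // 2
        p_half = float(spectrum.mean_power[half])
        if p_half / med >= prominence_threshold and p_half >= spectrum.mean_power[best] / 3.0:
            return half, p_half / med
    return best, prominence


def crown_spectrum_from_particles(
    subtomos,
    particles,
    radius_band_nm: tuple,
    height_band_nm: tuple,
    n_samples: int = 128,
) -> AngularPowerSpectrum:
    """Averaged angular power spectrum over individually analyzed particles.

    Each particle's profile is taken about its own (refined) axis; because
    power spectra are invariant to the azimuthal phase, detection does not
    require azimuthal registration across particles.
    """
    profiles = []
    for sub, p in zip(subtomos, particles):
        profiles.append(
            angular_intensity_profile(
                sub,
                radius_band_nm,
                height_band_nm,
                n_samples=n_samples,
                euler_zyz_deg=p.euler_zyz_deg,
            )
        )
    spec = rotational_power_spectrum(profiles)
    spec.radius_band_nm = radius_band_nm
    spec.height_band_nm = height_band_nm
    return spec
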