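"""Synthetic ground-truth generators for the spherule/crown tomography pipeline.

This module is the study-condition generator: planar outer membranes carrying
~30-70 nm invaginated spherule vesicles filled with a worm-like-chain dsRNA
coil at ~6.4 nm center-to-center spacing, necked apertures crowned by a
C12 turret-and-teeth structure (19 nm turret, 35 nm tooth ring, 11 nm open
channel, 14 nm height), and a forward model that corrupts the clean density
with a +/-60 degree missing wedge and additive Gaussian noise at a chosen
SNR.  Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import DensityVolume, Particle, ParticleSet

__all__ = [
    "CrownSpec",
    "SpheruleSpec",
    "TiltGeometry",
    "NoiseModel",
    "SpheruleGroundTruth",
    "make_crown_density",
    "make_spherule_phantom",
    "make_tomogram",
    "make_crown_particle_stack",
    "sample_volume_mixture",
    "missing_wedge_mask",
    "apply_missing_wedge",
    "add_noise",
]

MEMBRANE_THICKNESS_NM = 5.0  # lipid bilayer, leaflet-to-leaflet
FILAMENT_RADIUS_NM = 1.0  # dsRNA duplex radius


@dataclass(frozen=True)
class CrownSpec:
    """Geometry of the crown: a cupped turret ringed by discrete teeth.

    Defaults follow the subtomogram-averaged crown: ~19 nm turret diameter
    raised ~14 nm above the membrane, an ~11 nm open axial channel, and a
    ~35 nm diameter ring of 12 teeth projecting ~3 nm above the membrane.
    """

    turret_diameter_nm: float = 19.0
    turret_height_nm: float = 14.0
    channel_diameter_nm: float = 11.0
    teeth_count: int = 12
    teeth_ring_diameter_nm: float = 35.0
    teeth_height_nm: float = 3.0
    central_density: bool = True

    def __post_init__(self):
        if not (self.channel_diameter_nm < self.turret_diameter_nm < self.teeth_ring_diameter_nm):
            raise ValueError(
                "crown spec requires channel_diameter < turret_diameter < teeth_ring_diameter, got "
                f"{self.channel_diameter_nm}, {self.turret_diameter_nm}, {self.teeth_ring_diameter_nm}"
            )
        if self.teeth_count < 1:
            raise ValueError("teeth_count must be >= 1")


@dataclass(frozen=True)
class SpheruleSpec:
    """Geometry of one spherule: vesicle radius, interior coil, neck and crown."""

    radius_nm: float = 25.0
    filament_spacing_nm: float = 6.4
    filament_persistence_nm: float = 62.0  # midpoint of the 60-64 nm dsRNA range
    neck_diameter_nm: float = 11.0
    crown: CrownSpec = field(default_factory=CrownSpec)

    def __post_init__(self):
        if self.radius_nm <= self.neck_diameter_nm / 2:
            raise ValueError("spherule radius must exceed the neck radius")
        if self.filament_spacing_nm <= 0:
            raise ValueError("filament_spacing_nm must be positive")


@dataclass(frozen=True)
class TiltGeometry:
    """Tilt-series geometry determining the missing wedge.

    The tilt axis is an in-plane grid axis (default y); the unsampled region
    of Fourier space is the wedge within ``90 - tilt_max`` degrees of the
    beam (z) axis in the x-z Fourier plane.  ``increment_deg`` is carried as
    acquisition metadata; the wedge mask treats the sampled range as
    continuous, which is exact in the limit of fine increments.
    """

    tilt_min_deg: float = -60.0
    tilt_max_deg: float = 60.0
    increment_deg: float = 2.0
    wedge_axis: str = "y"

    def __post_init__(self):
        if not self.tilt_min_deg < self.tilt_max_deg:
            raise ValueError("tilt_min_deg must be < tilt_max_deg")
        if self.increment_deg <= 0:
            raise ValueError("increment_deg must be positive")
        if self.wedge_axis not in ("x", "y"):
            raise ValueError("wedge_axis (the tilt axis) must be 'x' or 'y'")

    @property
    def half_range_deg(self) -> float:
        return max(abs(self.tilt_min_deg), abs(self.tilt_max_deg))


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise pegged to a signal-to-noise ratio.

    ``snr`` is the ratio of signal variance (measured inside the structural
    support of the clean map) to noise variance.
    """

    snr: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.snr > 0:
            raise ValueError("snr must be positive")


# ---------------------------------------------------------------------------
# Crown rendering
# ---------------------------------------------------------------------------

def _crown_field(spec: CrownSpec, dz, dy, dx):
    """Analytic crown density (turret + teeth + optional central cone).

    ``dz, dy, dx`` are coordinate arrays in nm relative to the point where
    the crown axis pierces the membrane surface; +z is cytoplasmic.
    The field is an analytic function of position, so its only deviation from
    exact C(teeth_count) symmetry is voxelization.
    """
    r_xy = np.sqrt(dx**2 + dy**2)
    density = np.zeros(np.broadcast_shapes(dz.shape, dy.shape, dx.shape), dtype=np.float32)

    # Cup-shaped turret: a cylindrical wall between the open channel and the
    # turret outer surface, running from the membrane to turret_height.
    r_chan = spec.channel_diameter_nm / 2.0
    r_tur = spec.turret_diameter_nm / 2.0
    r_wall = 0.5 * (r_chan + r_tur)
    sigma_wall = max(0.6, (r_tur - r_chan) / 4.0)
    wall_radial = np.exp(-0.5 * ((r_xy - r_wall) / sigma_wall) ** 2)
    z_env = _smooth_band(dz, 0.0, spec.turret_height_nm, edge=1.0)
    density += wall_radial * z_env

    # Teeth: prolate Gaussian blobs on the outer ring, long axis tilted
    # slightly (15 degrees) toward the turret.
    r_ring = spec.teeth_ring_diameter_nm / 2.0
    tilt = np.deg2rad(15.0)
    sigma_long, sigma_perp = 2.5, 1.2
    for k in range(spec.teeth_count):
        ang = 2.0 * np.pi * k / spec.teeth_count
        cx, cy = r_ring * np.cos(ang), r_ring * np.sin(ang)
        cz = spec.teeth_height_nm
        # unit vector of the tooth long axis: up, leaning toward the axis
        ux = -np.sin(tilt) * np.cos(ang)
        uy = -np.sin(tilt) * np.sin(ang)
        uz = np.cos(tilt)
        px, py, pz = dx - cx, dy - cy, dz - cz
        along = px * ux + py * uy + pz * uz
        perp2 = px**2 + py**2 + pz**2 - along**2
        density += np.exp(-0.5 * (along / sigma_long) ** 2 - 0.5 * perp2 / sigma_perp**2)

    if spec.central_density:
        # Interior cone low in the cup: base at the membrane, apex at ~1/3 height.
        cone_h = spec.turret_height_nm / 3.0
        frac = np.clip(dz / cone_h, 0.0, 1.0)
        cone_r = 3.0 * (1.0 - frac)
        inside = (dz >= 0) & (dz <= cone_h)
        density += np.where(
            inside, np.exp(-0.5 * (r_xy / np.maximum(cone_r, 0.3)) ** 2) * _smooth_band(dz, 0.0, cone_h, edge=0.8), 0.0
        )
    return density


def _smooth_band(z, lo, hi, edge=1.0):
    """~1 inside [lo, hi], rolling off smoothly over ``edge`` nm outside."""
    return 1.0 / (1.0 + np.exp(-(z - lo) / (edge / 4.0))) / (1.0 + np.exp((z - hi) / (edge / 4.0)))


def _membrane_slab(dz, r_xy=None, hole_radius_nm=None):
    """Gaussian-profile membrane slab centered just below the surface plane."""
    sigma = MEMBRANE_THICKNESS_NM / 2.355  # FWHM = thickness
    slab = 0.8 * np.exp(-0.5 * ((dz + MEMBRANE_THICKNESS_NM / 2.0) / sigma) ** 2)
    if hole_radius_nm is not None:
        slab = slab * (1.0 - _radial_disk(r_xy, hole_radius_nm))
    return slab


def _radial_disk(r_xy, radius, edge=1.0):
    return 1.0 / (1.0 + np.exp((r_xy - radius) / (edge / 4.0)))


def _grid_nm(box_edge_vox: int, voxel_size_nm: float):
    """Centered coordinate arrays (dz, dy, dx) in nm for a cubic box."""
    c = (box_edge_vox - 1) / 2.0
    ax = (np.arange(box_edge_vox) - c) * voxel_size_nm
    return ax[:, None, None], ax[None, :, None], ax[None, None, :]


def make_crown_density(
    spec: CrownSpec = CrownSpec(),
    voxel_size_nm: float = 1.0,
    box_edge_vox: int = 48,
) -> DensityVolume:
    """Render a noiseless crown-on-membrane map with exact C(teeth_count) symmetry.

    The membrane surface sits ``turret_height/2`` below the box center so the
    turret spans the center symmetrically.  Raises if the box cannot contain
    the tooth ring plus a 4 nm margin.
    """
    extent = box_edge_vox * voxel_size_nm
    if extent < spec.teeth_ring_diameter_nm + 8.0:
        raise ValueError(
            f"box extent {extent:.1f} nm too small for teeth ring {spec.teeth_ring_diameter_nm:.1f} nm"
            " plus 4 nm margin on each side"
        )
    dz, dy, dx = _grid_nm(box_edge_vox, voxel_size_nm)
    z_surf = -spec.turret_height_nm / 2.0  # membrane surface plane relative to box center
    zz = dz - z_surf
    r_xy = np.sqrt(dx**2 + dy**2)
    data = _crown_field(spec, zz, dy, dx) + _membrane_slab(zz, r_xy, hole_radius_nm=spec.channel_diameter_nm / 2.0)
    data = ndimage.gaussian_filter(data.astype(np.float32), sigma=0.5)
    return DensityVolume(data, voxel_size_nm)


# ---------------------------------------------------------------------------
# Spherule phantom with worm-like-chain filament
# ---------------------------------------------------------------------------

@dataclass
class SpheruleGroundTruth:
    """Generator truth accompanying a spherule phantom.

    ``filament_path_nm`` is the ordered polyline of the interior coil in nm
    (z,y,x) relative to the box origin; ``crown_center_vox`` / ``crown_euler``
    give the crown pose (axis +z before external posing); ``radius_nm`` is the
    vesicle radius measured to the membrane midplane.
    """

    filament_path_nm: np.ndarray
    crown_center_vox: np.ndarray
    crown_euler_zyz_deg: np.ndarray
    radius_nm: float
    center_vox: np.ndarray


def _grow_wlc_coil(radius_nm, spacing_nm, persistence_nm, rng, step_nm=1.6, max_tries=40):
    """Grow a self-avoiding worm-like chain confined to a sphere.

    The chain is laid down until the mean nearest-neighbor center-to-center
    distance of its points (excluding same-strand points within one
    persistence length of arc) falls to the target spacing.  Returns an
    (N, 3) array of xyz points in nm, centered on the sphere center.
    Raises if the target spacing is unreachable for the given radius.
    """
    r_max = radius_nm - MEMBRANE_THICKNESS_NM / 2.0 - FILAMENT_RADIUS_NM
    if r_max < spacing_nm:
        raise ValueError(
            f"spacing {spacing_nm} nm unreachable inside radius {radius_nm} nm: interior too small"
        )
    hard_core = 0.8 * spacing_nm
    # generous capacity bound: hexagonal parallel-cylinder packing
    max_points = int(8.0 * (4.0 / 3.0) * np.pi * r_max**3 / (spacing_nm**2 * step_nm))

    pos = rng.normal(size=3)
    pos = pos / np.linalg.norm(pos) * 0.3 * r_max
    tangent = rng.normal(size=3)
    tangent /= np.linalg.norm(tangent)
    points = [pos.copy()]
    theta_sd = np.sqrt(2.0 * step_nm / persistence_nm)
    # same-strand exclusion window: a short arc of recent steps whose hard-core
    # clash with the growing tip is geometric, not packing
    excl_steps = max(3, int(round(1.5 * spacing_nm / step_nm)))

    def packing_measure(pts):
        # same-strand pairs within one persistence length of arc are excluded,
        # mirroring the downstream spacing estimator; for short chains the
        # window shrinks so the measure stays defined
        n = len(pts)
        excl_eff = int(min(round(persistence_nm / step_nm), max(2 * excl_steps, n // 3)))
        return _mean_nn_spacing(pts, step_nm, excl_eff)

    tree = None  # KD-tree over points[:m_tree] ("old" points at last rebuild)
    m_tree = 0
    check_every = 40
    backtracks = 0
    consecutive_stalls = 0
    max_backtracks = 5000
    since_check = 0
    while len(points) < max_points:
        placed = False
        for attempt in range(max_tries):
            # bend: Gaussian polar angle about the current tangent, random azimuth;
            # widen the proposal cone as attempts fail so the chain can escape traps
            if attempt < 25:
                widen = 1.0 + attempt / 5.0
                theta = abs(rng.normal(0.0, theta_sd * widen))
                phi = rng.uniform(0.0, 2.0 * np.pi)
                t_new = _bend(tangent, theta, phi)
            else:
                t_new = rng.normal(size=3)  # last resort: any direction
                t_new /= np.linalg.norm(t_new)
            cand = points[-1] + step_nm * t_new
            rr = np.linalg.norm(cand)
            if rr > r_max:
                # bounce off the confining sphere
                normal = cand / rr
                t_ref = t_new - 2.0 * np.dot(t_new, normal) * normal
                cand = points[-1] + step_nm * t_ref
                if np.linalg.norm(cand) > r_max:
                    continue
                t_new = t_ref
            # self-avoidance against all points older than the exclusion window
            n_old = len(points) - excl_steps
            clash = False
            if m_tree > 0:
                d, _ = tree.query(cand, k=1)
                clash = d < hard_core
            if not clash and n_old > m_tree:
                clash = _min_dist_to_slice(points, cand, m_tree, n_old) < hard_core
            if clash:
                continue
            points.append(cand)
            tangent = t_new
            placed = True
            consecutive_stalls = 0
            since_check += 1
            break
        if not placed:
            # A stalled tip in an otherwise full sphere usually means the coil
            # is already at its packing target between periodic checks.
            mean_nn = packing_measure(np.asarray(points))
            if mean_nn is not None and mean_nn <= 1.08 * spacing_nm:
                break
            # dead end: retract a stretch of chain and regrow along a new path,
            # retracting deeper each consecutive stall to escape large pockets
            backtracks += 1
            consecutive_stalls += 1
            if backtracks > max_backtracks:
                raise ValueError(
                    f"filament growth stalled before reaching spacing {spacing_nm} nm "
                    f"(radius {radius_nm} nm, {len(points)} points placed)"
                )
            depth = min(8 * consecutive_stalls, 150)
            if len(points) > 1:
                del points[-min(depth, len(points) - 1):]
            if len(points) >= 2:
                tangent = points[-1] - points[-2]
                tangent /= np.linalg.norm(tangent)
            else:
                tangent = rng.normal(size=3)
                tangent /= np.linalg.norm(tangent)
            m_tree = max(0, len(points) - excl_steps)
            tree = cKDTree(points[:m_tree]) if m_tree > 0 else None
            continue
        if since_check >= check_every:
            since_check = 0
            m_tree = max(0, len(points) - excl_steps)
            if m_tree > 0:
                tree = cKDTree(points[:m_tree])
            mean_nn = packing_measure(np.asarray(points))
            if mean_nn is not None and mean_nn <= 1.02 * spacing_nm:
                break
    pts = np.asarray(points)
    mean_nn = packing_measure(pts)
    if mean_nn is None or not (0.9 * spacing_nm <= mean_nn <= 1.1 * spacing_nm):
        raise ValueError(
            f"filament coil did not reach target spacing {spacing_nm} nm "
            f"(achieved {mean_nn}) for radius {radius_nm} nm"
        )
    return pts


def _bend(tangent, theta, phi):
    """Rotate ``tangent`` away from itself by polar angle theta, azimuth phi."""
    t = tangent / np.linalg.norm(tangent)
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return np.cos(theta) * t + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _min_dist_to_slice(points, cand, lo, hi):
    block = np.asarray(points[lo:hi])
    if len(block) == 0:
        return np.inf
    return float(np.min(np.linalg.norm(block - cand, axis=1)))


def _mean_nn_spacing(pts, step_nm, excl_steps):
    """Mean nearest-neighbor distance excluding same-strand arc neighbors."""
    n = len(pts)
    if n < 2 * excl_steps + 4:
        return None
    tree = cKDTree(pts)
    k = min(n, 4 * excl_steps)
    dists, idx = tree.query(pts, k=k)
    out = []
    rows = np.arange(n)
    for i in rows:
        for d, j in zip(dists[i], idx[i]):
            if abs(int(j) - i) > excl_steps:
                out.append(d)
                break
    if len(out) < n // 2:
        return None
    return float(np.mean(out))


def make_spherule_phantom(
    spec: SpheruleSpec = SpheruleSpec(),
    voxel_size_nm: float = 1.0,
    seed: int | None = 0,
    box_edge_vox: int | None = None,
    include_crown: bool = True,
    include_filament: bool = True,
) -> tuple[DensityVolume, SpheruleGroundTruth]:
    """Render one spherule: invaginated vesicle, neck, interior coil and crown.

    The planar outer membrane lies near the box top with its normal along +z;
    the vesicle hangs below it, connected through an open neck, and the crown
    sits on the cytoplasmic (upper) side.  Identical (spec, seed) inputs give
    bit-identical outputs.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible phantom generation")
    rng = np.random.default_rng(seed)
    R = spec.radius_nm
    need = 2 * R + 24.0
    if box_edge_vox is None:
        box_edge_vox = int(np.ceil(max(need, spec.crown.teeth_ring_diameter_nm + 10) / voxel_size_nm))
        box_edge_vox += box_edge_vox % 2
    dz, dy, dx = _grid_nm(box_edge_vox, voxel_size_nm)
    c = (box_edge_vox - 1) / 2.0

    neck_r = spec.neck_diameter_nm / 2.0
    neck_len = 4.0
    # membrane surface plane placed so vesicle + crown fit centered-ish
    z_surf = R + neck_len - (2 * R + neck_len) / 2.0  # center of mass of vesicle+membrane at 0
    z_center = z_surf - neck_len - R  # vesicle center
    zz = dz - z_surf
    r_xy = np.sqrt(dx**2 + dy**2)

    data = _membrane_slab(zz, r_xy, hole_radius_nm=neck_r)

    # vesicle shell: Gaussian-profile sphere, opened where the neck attaches
    r_sph = np.sqrt(dx**2 + dy**2 + (dz - z_center) ** 2)
    sigma_mem = MEMBRANE_THICKNESS_NM / 2.355
    shell = 0.8 * np.exp(-0.5 * ((r_sph - R) / sigma_mem) ** 2)
    cap = _radial_disk(r_xy, neck_r + 1.0) * _smooth_band(dz - z_center, 0.6 * R, 2 * R, edge=2.0)
    data += shell * (1.0 - cap)

    # neck tube wall from vesicle top to the membrane plane
    wall = 0.8 * np.exp(-0.5 * ((r_xy - neck_r) / 0.8) ** 2)
    data += wall * _smooth_band(dz - (z_center + R - 2.0), 0.0, neck_len + 4.0, edge=1.0)

    path_nm = np.zeros((0, 3))
    if include_filament:
        pts_xyz = _grow_wlc_coil(R, spec.filament_spacing_nm, spec.filament_persistence_nm, rng)
        # to absolute nm coordinates in z,y,x order
        path_nm = np.column_stack(
            [
                pts_xyz[:, 2] + z_center + c * voxel_size_nm,
                pts_xyz[:, 1] + c * voxel_size_nm,
                pts_xyz[:, 0] + c * voxel_size_nm,
            ]
        )
        _splat_filament(data, path_nm, voxel_size_nm, amplitude=1.0, sigma_nm=0.9)

    if include_crown:
        data += _crown_field(spec.crown, zz, dy, dx)

    data = ndimage.gaussian_filter(data.astype(np.float32), sigma=0.5)
    vol = DensityVolume(data, voxel_size_nm)
    truth = SpheruleGroundTruth(
        filament_path_nm=path_nm,
        crown_center_vox=np.array([z_surf / voxel_size_nm + c, c, c]),
        crown_euler_zyz_deg=np.zeros(3),
        radius_nm=R,
        center_vox=np.array([z_center / voxel_size_nm + c, c, c]),
    )
    return vol, truth


def _splat_filament(data, path_nm, voxel_size_nm, amplitude=1.0, sigma_nm=0.9):
    """Accumulate Gaussian density along a polyline, in place."""
    sigma_vox = sigma_nm / voxel_size_nm
    half = int(np.ceil(3 * sigma_vox))
    offs = np.arange(-half, half + 1)
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
    shape = data.shape
    for p in path_nm:
        pv = p / voxel_size_nm
        base = np.round(pv).astype(int)
        fz, fy, fx = pv - base
        kern = amplitude * np.exp(-0.5 * ((oz - fz) ** 2 + (oy - fy) ** 2 + (ox - fx) ** 2) / sigma_vox**2)
        zs, ys, xs = base[0] + oz, base[1] + oy, base[2] + ox
        valid = (
            (zs >= 0) & (zs < shape[0]) & (ys >= 0) & (ys < shape[1]) & (xs >= 0) & (xs < shape[2])
        )
        np.add.at(data, (zs[valid], ys[valid], xs[valid]), kern[valid])


# ---------------------------------------------------------------------------
# Missing wedge and noise
# ---------------------------------------------------------------------------

def missing_wedge_mask(shape, tilt: TiltGeometry = TiltGeometry()) -> np.ndarray:
    """Boolean Fourier mask (np.fft layout, unshifted): True where sampled.

    With tilt axis y, a spatial frequency is sampled when the angle of its
    (f_x, f_z) projection from the f_x plane does not exceed the tilt range;
    the missing wedge is the complement, hugging the f_z axis.
    """
    nz, ny, nx = shape
    if tilt.half_range_deg >= 90.0:
        return np.ones(shape, dtype=bool)  # full tilt range: nothing missing
    fz = np.fft.fftfreq(nz)[:, None, None]
    fy = np.fft.fftfreq(ny)[None, :, None]
    fx = np.fft.fftfreq(nx)[None, None, :]
    if tilt.wedge_axis == "y":
        in_plane, out_plane = fx, fz
    else:
        in_plane, out_plane = fy, fz
    ang = np.degrees(np.arctan2(np.abs(out_plane), np.abs(in_plane)))
    mask = ang <= tilt.half_range_deg + 1e-9
    return np.broadcast_to(mask, shape).copy()


def apply_missing_wedge(vol: DensityVolume, tilt: TiltGeometry = TiltGeometry()) -> DensityVolume:
    """Zero all Fourier components inside the missing wedge (idempotent)."""
    mask = missing_wedge_mask(vol.data.shape, tilt)
    f = np.fft.fftn(vol.data)
    out = np.real(np.fft.ifftn(f * mask)).astype(np.float32)
    return DensityVolume(out, vol.voxel_size_nm, vol.origin_nm.copy())


def _signal_support(clean: np.ndarray) -> np.ndarray:
    amax = np.abs(clean).max()
    if amax == 0:
        return np.ones_like(clean, dtype=bool)
    return np.abs(clean) > 0.05 * amax


def add_noise(vol: DensityVolume, noise: NoiseModel, support: np.ndarray | None = None) -> DensityVolume:
    """Add white Gaussian noise scaled so signal_var/noise_var = snr.

    Signal variance is measured inside the structural support (by default,
    voxels above 5% of the peak absolute density).
    """
    rng = np.random.default_rng(noise.seed)
    if support is None:
        support = _signal_support(vol.data)
    sig_var = float(np.var(vol.data[support]))
    if sig_var == 0:
        raise ValueError("cannot set SNR on a zero-variance signal")
    sigma = np.sqrt(sig_var / noise.snr)
    noisy = vol.data + rng.normal(0.0, sigma, size=vol.data.shape).astype(np.float32)
    return DensityVolume(noisy.astype(np.float32), vol.voxel_size_nm, vol.origin_nm.copy())


# ---------------------------------------------------------------------------
# Tomogram assembly and particle stacks
# ---------------------------------------------------------------------------

def make_tomogram(
    phantoms: list[tuple[DensityVolume, SpheruleGroundTruth, np.ndarray, float]],
    tilt: TiltGeometry = TiltGeometry(),
    noise: NoiseModel | None = NoiseModel(),
    shape: tuple[int, int, int] | None = None,
) -> tuple[DensityVolume, ParticleSet]:
    """Sum posed spherule phantoms into one volume and corrupt it.

    Each phantom entry is ``(volume, truth, position_vox, azimuth_deg)``:
    the phantom box center is placed at ``position_vox`` (z,y,x) in the target
    volume after rotating the phantom about its +z axis by ``azimuth_deg``.
    Corruption: missing-wedge filtering per ``tilt`` then additive noise per
    ``noise`` (skip noise with ``noise=None``).  Returns the tomogram and a
    ground-truth particle set (crown positions, membrane-normal orientations).
    """
    if not phantoms:
        raise ValueError("no phantoms to place")
    voxel = phantoms[0][0].voxel_size_nm
    if shape is None:
        edge = max(max(v.data.shape) for v, *_ in phantoms)
        n = len(phantoms)
        side = int(np.ceil(np.sqrt(n)))
        shape = (edge, side * edge, side * edge)
    target = np.zeros(shape, dtype=np.float32)

    # overlap check on bounding spheres
    centers = [np.asarray(p[2], dtype=float) for p in phantoms]
    radii = [max(v.data.shape) * np.sqrt(3) / 2 * 0.55 for v, *_ in phantoms]
    for i in range(len(phantoms)):
        for j in range(i + 1, len(phantoms)):
            if np.linalg.norm(centers[i] - centers[j]) < 0.9 * (radii[i] + radii[j]) / np.sqrt(3):
                raise ValueError(f"phantoms {i} and {j} overlap")

    particles = []
    for vol, truth, pos, azimuth in phantoms:
        arr = vol.data
        if azimuth % 360.0 != 0.0:
            arr = ndimage.rotate(arr, angle=-azimuth, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0)
        _paste_add(target, arr, np.asarray(pos, dtype=float))
        crown_off = truth.crown_center_vox - (np.array(vol.data.shape) - 1) / 2.0
        crown_pos = np.asarray(pos, dtype=float) + crown_off  # crown axis is +z; azimuth spins x,y only... offset is axial
        particles.append(
            Particle(
                position_vox=crown_pos,
                euler_zyz_deg=np.zeros(3),
                true_euler_zyz_deg=np.array([0.0, 0.0, azimuth % 360.0]),
            )
        )
    tomo = DensityVolume(target, voxel)
    support = _signal_support(tomo.data)
    tomo = apply_missing_wedge(tomo, tilt)
    if noise is not None:
        tomo = add_noise(tomo, noise, support=support)
    pset = ParticleSet(particles, source_volume="synthetic tomogram")
    pset.log(f"make_tomogram: {len(particles)} phantoms, tilt +/-{tilt.half_range_deg} deg, "
             f"snr {'inf' if noise is None else noise.snr}")
    return tomo, pset


def _paste_add(target, block, center_vox):
    """Add ``block`` into ``target`` with the block center at center_vox."""
    bshape = np.array(block.shape)
    start = np.round(center_vox - (bshape - 1) / 2.0).astype(int)
    tsl, bsl = [], []
    for ax in range(3):
        t0 = max(start[ax], 0)
        t1 = min(start[ax] + bshape[ax], target.shape[ax])
        if t1 <= t0:
            return
        b0 = t0 - start[ax]
        tsl.append(slice(t0, t1))
        bsl.append(slice(b0, b0 + (t1 - t0)))
    target[tuple(tsl)] += block[tuple(bsl)]


def make_crown_particle_stack(
    spec: CrownSpec = CrownSpec(),
    n_particles: int = 100,
    snr: float | None = 0.5,
    tilt: TiltGeometry = TiltGeometry(),
    voxel_size_nm: float = 1.0,
    box_edge_vox: int = 48,
    seed: int = 0,
    tilt_jitter_deg: float = 2.0,
) -> tuple[list[DensityVolume], ParticleSet]:
    """Simulate extracted crown subtomograms at random azimuths.

    Each particle is the clean crown map spun by a uniform random azimuth
    (plus a small random axis tilt emulating membrane-normal picking error),
    wedge-filtered, and degraded with fresh noise at ``snr`` (``None`` for
    noiseless).  Particles carry ground-truth orientations and identity
    initial orientations (membrane normal along +z, azimuth 0).
    """
    from .align import rotate_volume  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    clean = make_crown_density(spec, voxel_size_nm, box_edge_vox)
    support = _signal_support(clean.data)
    sig_var = float(np.var(clean.data[support]))
    subtomos, particles = [], []
    center = (np.array(clean.data.shape) - 1) / 2.0
    for i in range(n_particles):
        azimuth = rng.uniform(0.0, 360.0)
        tilt_mag = abs(rng.normal(0.0, tilt_jitter_deg / 2.0)) if tilt_jitter_deg > 0 else 0.0
        tilt_az = rng.uniform(0.0, 360.0)
        true_euler = np.array([tilt_az, tilt_mag, azimuth - tilt_az])
        posed = rotate_volume(clean, true_euler, cval=0.0)
        posed = apply_missing_wedge(posed, tilt)
        if snr is not None:
            sigma = np.sqrt(sig_var / snr)
            posed = DensityVolume(
                (posed.data + rng.normal(0.0, sigma, posed.data.shape)).astype(np.float32),
                voxel_size_nm,
            )
        subtomos.append(posed)
        particles.append(
            Particle(
                position_vox=center.copy(),
                euler_zyz_deg=np.zeros(3),
                half_set="A" if i % 2 == 0 else "B",
                true_euler_zyz_deg=true_euler,
            )
        )
    pset = ParticleSet(particles, source_volume="synthetic crown stack")
    pset.log(
        f"make_crown_particle_stack: n={n_particles}, snr={snr}, box={box_edge_vox}, seed={seed}"
    )
    return subtomos, pset


# ---------------------------------------------------------------------------
# Volume mixture sampler
# ---------------------------------------------------------------------------

def sample_volume_mixture(
    component_means_nm3,
    component_sds_nm3,
    weights,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw spherule volumes from a Gaussian mixture, truncated at > 0.

    Emulates measured spherule-volume distributions (e.g. the two RNA1-
    associated size classes near 108,000 and 12,000 nm^3).
    """
    means = np.asarray(component_means_nm3, dtype=float)
    sds = np.asarray(component_sds_nm3, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if n <= 0:
        raise ValueError("n must be positive")
    if means.shape != sds.shape or means.shape != weights.shape:
        raise ValueError("means, sds, weights must have matching shapes")
    if np.any(means <= 0) or np.any(sds < 0):
        raise ValueError("means must be > 0 and sds >= 0")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError(f"weights must sum to 1, got {weights.sum()}")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), size=n, p=weights)
    draws = rng.normal(means[comp], sds[comp])
    bad = draws <= 0
    while np.any(bad):
        draws[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = draws <= 0
    return draws
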