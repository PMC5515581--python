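"""Subtomogram extraction, orientation priors, and iterative cone-search alignment.

The refinement follows the classic constrained scheme: each particle starts
from the membrane normal, poses are scanned over a cone of axes (spiral
sampling, no pole oversampling) crossed with an azimuth scan, matching is
wedge-masked normalized cross-correlation with an FFT shift search bounded by
a hard shift limit, and the evolving average is built with Fourier coverage
weighting so the missing wedge of individual particles does not bias the
result.  Half sets A/B can be refined fully independently (gold standard).
No symmetry is imposed at any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .phantom import TiltGeometry, missing_wedge_mask
from .volumes import (
    DensityVolume,
    Particle,
    ParticleSet,
    euler_to_matrix,
    matrix_to_euler,
)

__all__ = [
    "AlignmentConfig",
    "SubtomogramAverage",
    "PlanarMembrane",
    "extract_subtomogram",
    "initial_orientations_from_normals",
    "rotate_volume",
    "score_pose",
    "search_best_pose",
    "align_iterate",
    "initial_template",
    "cone_directions",
]


@dataclass
class AlignmentConfig:
    """Search schedule and matching options for iterative refinement.

    The cone half-angle narrows over iterations (60 deg down to 5 deg, after
    the published schedule); the azimuth is scanned over the full 360 deg on
    the first iteration and thereafter within the current cone half-angle on
    either side of the previous azimuth.  Shifts are bounded by
    ``shift_limit_vox`` around the original particle position.
    """

    box_edge_vox: int = 48
    cone_halfangle_schedule_deg: tuple = (60.0, 30.0, 15.0, 8.0, 5.0)
    angular_step_schedule_deg: tuple = (30.0, 15.0, 8.0, 4.0, 2.5)
    azimuth_range_deg: float = 360.0
    shift_limit_vox: float = 5.0
    max_iterations: int = 12
    lowpass_nm: float = 6.6
    wedge_compensation: bool = True
    gold_standard: bool = True
    tilt: TiltGeometry = field(default_factory=TiltGeometry)

    def __post_init__(self):
        cones = np.asarray(self.cone_halfangle_schedule_deg, dtype=float)
        steps = np.asarray(self.angular_step_schedule_deg, dtype=float)
        if len(cones) != len(steps):
            raise ValueError("cone and angular-step schedules must have equal length")
        if np.any(np.diff(cones) > 0) or np.any(np.diff(steps) > 0):
            raise ValueError("schedules must be non-increasing")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.shift_limit_vox < 0:
            raise ValueError("shift_limit_vox must be >= 0")

    def stage(self, iteration: int) -> tuple[float, float]:
        """(cone half-angle, angular step) for a 0-based iteration index."""
        i = min(iteration, len(self.cone_halfangle_schedule_deg) - 1)
        return (
            float(self.cone_halfangle_schedule_deg[i]),
            float(self.angular_step_schedule_deg[i]),
        )


@dataclass
class SubtomogramAverage:
    """Refined average with its two independently refined half maps."""

    map: DensityVolume
    n_particles: int
    half_map_A: DensityVolume
    half_map_B: DensityVolume
    config_used: AlignmentConfig
    iteration_log: list = field(default_factory=list)


@dataclass
class PlanarMembrane:
    """A flat membrane model: a surface point and outward normal (x,y,z)."""

    point_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))  # (z,y,x)
    normal_xyz: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.point_nm = np.asarray(self.point_nm, dtype=float)
        n = np.asarray(self.normal_xyz, dtype=float)
        self.normal_xyz = n / np.linalg.norm(n)

    def normal_at(self, pos_nm_zyx) -> np.ndarray:
        return self.normal_xyz

    def distance(self, pos_nm_zyx) -> float:
        d_zyx = np.asarray(pos_nm_zyx, dtype=float) - self.point_nm
        d_xyz = d_zyx[::-1]
        return float(abs(np.dot(d_xyz, self.normal_xyz)))


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _rotate_array(arr: np.ndarray, matrix_xyz: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Rotate a (z,y,x) array about its center by a rotation matrix in xyz space.

    The output at voxel v equals the input at R^-1 v, i.e. content is rotated
    forward by R.  Trilinear interpolation by default.
    """
    m_zyx = matrix_xyz.T[::-1, ::-1]
    center = (np.array(arr.shape) - 1) / 2.0
    offset = center - m_zyx @ center
    return ndimage.affine_transform(arr, m_zyx, offset=offset, order=order, mode="constant", cval=cval)


def rotate_volume(vol: DensityVolume, euler_zyz_deg, order: int = 1, cval: float | None = None) -> DensityVolume:
    """Rotate a volume about its box center by an intrinsic Z-Y-Z triple.

    Voxels leaving the support are filled with the volume mean unless ``cval``
    is given.
    """
    fill = float(vol.data.mean()) if cval is None else cval
    R = euler_to_matrix(euler_zyz_deg)
    out = _rotate_array(vol.data.astype(np.float32), R, order=order, cval=fill)
    return DensityVolume(out.astype(np.float32), vol.voxel_size_nm, vol.origin_nm.copy())


def extract_subtomogram(
    vol: DensityVolume,
    particle: Particle,
    box_edge_vox: int,
    pad: bool = False,
    mean_subtract: bool = False,
    apodize: bool = False,
) -> DensityVolume:
    """Copy the cubic box centered on a particle out of a larger volume.

    With ``pad`` enabled, out-of-bounds voxels are filled with the volume
    mean; otherwise a box crossing the boundary is an error.  Optional
    preprocessing: mean subtraction and a cosine edge apodization.
    """
    center = np.round(particle.position_vox).astype(int)
    half = box_edge_vox // 2
    start = center - half
    stop = start + box_edge_vox
    if not pad and (np.any(start < 0) or np.any(stop > np.array(vol.data.shape))):
        raise ValueError(
            f"box {box_edge_vox} at particle position {center} exceeds volume bounds "
            f"{vol.data.shape}; enable pad to fill with the volume mean"
        )
    fill = float(vol.data.mean())
    out = np.full((box_edge_vox,) * 3, fill, dtype=np.float32)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(stop, np.array(vol.data.shape))
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = vol.data[
            src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
        ]
    if mean_subtract:
        out -= out.mean()
    if apodize:
        out *= _apodization_window(box_edge_vox)
    return DensityVolume(out, vol.voxel_size_nm)


def _apodization_window(n: int, edge_frac: float = 0.15) -> np.ndarray:
    """Separable cosine-edge window easing box boundaries toward zero."""
    edge = max(2, int(n * edge_frac))
    w = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    w[:edge] = ramp
    w[-edge:] = ramp[::-1]
    return (w[:, None, None] * w[None, :, None] * w[None, None, :]).astype(np.float32)


def initial_orientations_from_normals(
    particles: ParticleSet,
    membrane: PlanarMembrane,
    voxel_size_nm: float = 1.0,
    max_distance_nm: float = 20.0,
) -> ParticleSet:
    """Set each particle's orientation from the local outward membrane normal.

    The resulting rotation carries the reference +z axis onto the normal with
    zero twist; the azimuth is left at 0.  Particles farther than
    ``max_distance_nm`` from the membrane are flagged in the provenance log
    and keep their original orientation.
    """
    out, flagged = [], []
    z = np.array([0.0, 0.0, 1.0])
    for i, p in enumerate(particles):
        pos_nm = p.position_vox * voxel_size_nm
        if membrane.distance(pos_nm) > max_distance_nm:
            flagged.append(i)
            out.append(p)
            continue
        n = membrane.normal_at(pos_nm)
        n = n / np.linalg.norm(n)
        axis = np.cross(z, n)
        s = np.linalg.norm(axis)
        c = float(np.dot(z, n))
        if s < 1e-12:
            R = np.eye(3) if c > 0 else euler_to_matrix([0.0, 180.0, 0.0])
        else:
            from scipy.spatial.transform import Rotation

            R = Rotation.from_rotvec(axis / s * np.arctan2(s, c)).as_matrix()
        out.append(p.with_pose(euler_zyz_deg=matrix_to_euler(R)))
    ps = ParticleSet(out, particles.source_volume, list(particles.provenance))
    ps.log(f"initial orientations from membrane normals; flagged far particles: {flagged}")
    return ps


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _lowpass_filter(shape, voxel_size_nm: float, lowpass_nm: float | None) -> np.ndarray:
    """Gaussian low-pass with half-power at 1/lowpass_nm (np.fft layout)."""
    if lowpass_nm is None or lowpass_nm <= 0:
        return np.ones(shape, dtype=np.float32)
    axes = [np.fft.fftfreq(n, d=voxel_size_nm) for n in shape]
    f2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    fc = 1.0 / lowpass_nm
    return np.exp(-np.log(2.0) * f2 / fc**2).astype(np.float32)


def _fourier_weight(shape, voxel_size_nm, lowpass_nm, wedge_mask=None) -> np.ndarray:
    w = _lowpass_filter(shape, voxel_size_nm, lowpass_nm)
    if wedge_mask is not None:
        w = w * wedge_mask.astype(np.float32)
    w[0, 0, 0] = 0.0  # mean-free correlation
    return w


def score_pose(
    subtomo: DensityVolume,
    template: DensityVolume,
    euler_zyz_deg,
    shift_vox=(0.0, 0.0, 0.0),
    wedge_mask: np.ndarray | None = None,
    lowpass_nm: float | None = None,
) -> float:
    """Wedge-masked normalized cross-correlation for one explicit pose.

    The template is rotated by ``euler`` and shifted by ``shift_vox`` (z,y,x)
    before comparison.  Correlation is computed over mean-free Fourier
    components, restricted to outside the missing wedge when a wedge mask is
    supplied, and is invariant to affine intensity rescaling of either input.
    """
    if subtomo.data.shape != template.data.shape:
        raise ValueError("subtomogram and template must share a box size")
    posed = rotate_volume(template, euler_zyz_deg, cval=0.0).data
    w = _fourier_weight(subtomo.data.shape, subtomo.voxel_size_nm, lowpass_nm, wedge_mask)
    fa = np.fft.fftn(subtomo.data) * w
    fb = np.fft.fftn(posed) * w
    shift = np.asarray(shift_vox, dtype=float)
    if np.any(shift != 0):
        phase = _shift_phase(subtomo.data.shape, shift)
        fb = fb * phase
    na = np.linalg.norm(fa)
    nb = np.linalg.norm(fb)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance input to score_pose")
    return float(np.real(np.vdot(fa, fb)) / (na * nb))


def _shift_phase(shape, shift_zyx):
    fz = np.fft.fftfreq(shape[0])[:, None, None]
    fy = np.fft.fftfreq(shape[1])[None, :, None]
    fx = np.fft.fftfreq(shape[2])[None, None, :]
    return np.exp(-2j * np.pi * (fz * shift_zyx[0] + fy * shift_zyx[1] + fx * shift_zyx[2]))


def _shift_ball_mask(shape, limit: float) -> np.ndarray:
    """Mask over the cross-correlation map: True where |shift| <= limit."""
    idx = []
    for n in shape:
        a = np.arange(n)
        a = np.where(a <= n // 2, a, a - n)  # signed shifts in fft layout
        idx.append(a)
    z, y, x = np.meshgrid(*idx, indexing="ij")
    return z**2 + y**2 + x**2 <= limit**2 + 1e-9


def _signed_shift(index, shape):
    out = []
    for i, n in zip(index, shape):
        out.append(i if i <= n // 2 else i - n)
    return np.array(out, dtype=float)


def cone_directions(halfangle_deg: float, step_deg: float) -> np.ndarray:
    """Approximately uniform axis directions within a cone about +z.

    Fibonacci-spiral sampling on the spherical cap, prefixed with the exact
    cone axis so ties deterministically prefer the unperturbed direction.
    """
    if halfangle_deg <= 0:
        return np.array([[0.0, 0.0, 1.0]])
    theta_c = np.deg2rad(halfangle_deg)
    cap_area_deg2 = 360.0**2 / np.pi * (1.0 - np.cos(theta_c))
    n = max(1, int(round(cap_area_deg2 / step_deg**2)))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    z = 1.0 - (1.0 - np.cos(theta_c)) * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = k * golden
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return np.vstack([[0.0, 0.0, 1.0], dirs])


def _perturbation_rotations(cone_deg, step_deg, az_lo, az_hi, az_step):
    """Rotation matrices R_axis(d) @ Rz(az) over the cone/azimuth grid."""
    from scipy.spatial.transform import Rotation

    z = np.array([0.0, 0.0, 1.0])
    azimuths = np.arange(az_lo, az_hi + 1e-9, az_step)
    rots = []
    for d in cone_directions(cone_deg, step_deg):
        axis = np.cross(z, d)
        s = np.linalg.norm(axis)
        if s < 1e-12:
            R_axis = np.eye(3)
        else:
            R_axis = Rotation.from_rotvec(axis / s * np.arctan2(s, float(d[2]))).as_matrix()
        for az in azimuths:
            Rz = Rotation.from_euler("Z", az, degrees=True).as_matrix()
            rots.append(R_axis @ Rz)
    return rots


def search_best_pose(
    subtomo_rotated: np.ndarray,
    template: np.ndarray,
    perturbations: list[np.ndarray],
    weight: np.ndarray,
    shift_limit_vox: float,
    template_ffts: list[np.ndarray] | None = None,
):
    """Best (perturbation index, shift, score) for one reference-frame subtomogram.

    ``subtomo_rotated`` must already be rotated into the reference frame of
    the current particle orientation; ``weight`` is the per-particle Fourier
    weight (rotated wedge x low-pass, DC zeroed).  The shift search runs over
    the full FFT correlation map masked to ``|shift| <= shift_limit_vox``.
    Ties break to the first-found lowest perturbation index.
    """
    shape = subtomo_rotated.shape
    dup = _hermitian_dup_weights(shape)
    fa = sfft.rfftn(subtomo_rotated.astype(np.float32)) * weight
    na = np.sqrt(np.sum(dup * np.abs(fa) ** 2))
    if na == 0:
        raise ValueError("zero-variance subtomogram")
    ball = _shift_ball_mask(shape, shift_limit_vox)
    best = (-np.inf, 0, np.zeros(3))
    for pi, R in enumerate(perturbations):
        if template_ffts is not None:
            fb = template_ffts[pi]
        else:
            fb = sfft.rfftn(_rotate_array(template, R).astype(np.float32))
        fbw = fb * weight
        nb = np.sqrt(np.sum(dup * np.abs(fbw) ** 2))
        if nb == 0:
            continue
        # product of two Hermitian spectra is Hermitian: irfftn gives the
        # exact real cross-correlation over all shifts
        corr = sfft.irfftn(fa * np.conj(fbw), s=shape) / (na * nb)
        corr *= subtomo_rotated.size  # undo ifft normalization of the sum
        masked = np.where(ball, corr, -np.inf)
        idx = np.unravel_index(int(np.argmax(masked)), masked.shape)
        sc = float(masked[idx])
        if sc > best[0] + 1e-12:
            best = (sc, pi, _signed_shift(idx, shape))
    return best


def _hermitian_dup_weights(shape) -> np.ndarray:
    """Multiplicity of each rfftn coefficient in the full spectrum."""
    nx = shape[-1]
    nxh = nx // 2 + 1
    dup = np.full((1, 1, nxh), 2.0, dtype=np.float32)
    dup[..., 0] = 1.0
    if nx % 2 == 0:
        dup[..., -1] = 1.0
    return dup


# ---------------------------------------------------------------------------
# Averaging and iteration
# ---------------------------------------------------------------------------

def _accumulate_average(subtomos, particles, indices, weight_shape, voxel, wedge_shifted, lowpass_nm):
    """Coverage-weighted average of particles rotated into the reference frame."""
    fsum = np.zeros(weight_shape, dtype=np.complex128)
    cov = np.zeros(weight_shape, dtype=np.float64)
    for i in indices:
        p = particles[i]
        R = euler_to_matrix(p.euler_zyz_deg)
        arr = subtomos[i]
        shift = _current_shift(p)
        if np.any(shift != 0):
            arr = np.real(np.fft.ifftn(np.fft.fftn(arr) * _shift_phase(arr.shape, -shift)))
        rot = _rotate_array(arr.astype(np.float64), R.T)
        wrot = _rotate_wedge(wedge_shifted, R.T) if wedge_shifted is not None else np.ones(weight_shape)
        fsum += np.fft.fftn(rot) * wrot
        cov += wrot
    avg_f = np.where(cov > 0.1, fsum / np.maximum(cov, 0.1), 0.0)
    if lowpass_nm:
        avg_f *= _lowpass_filter(weight_shape, voxel, lowpass_nm)
    return np.real(np.fft.ifftn(avg_f)).astype(np.float32)


def _current_shift(p: Particle) -> np.ndarray:
    return np.asarray(getattr(p, "_shift_vox", np.zeros(3)), dtype=float)


def _set_shift(p: Particle, shift):
    p._shift_vox = np.asarray(shift, dtype=float)


def _rotate_wedge(wedge_shifted: np.ndarray, matrix_xyz: np.ndarray) -> np.ndarray:
    """Rotate an fftshifted wedge mask and return it in unshifted layout."""
    rot = _rotate_array(wedge_shifted, matrix_xyz, order=1, cval=0.0)
    return np.fft.ifftshift(np.clip(rot, 0.0, 1.0))


def initial_template(subtomos, particles: ParticleSet, config: AlignmentConfig) -> DensityVolume:
    """Average raw particles at their initial (membrane-normal) orientations."""
    arrs = [s.data.astype(np.float64) - s.data.mean() for s in subtomos]
    voxel = subtomos[0].voxel_size_nm
    wedge_shifted = None
    if config.wedge_compensation:
        wedge_shifted = np.fft.fftshift(
            missing_wedge_mask(arrs[0].shape, config.tilt).astype(np.float32)
        )
    data = _accumulate_average(
        arrs, list(particles), range(len(arrs)), arrs[0].shape, voxel, wedge_shifted, config.lowpass_nm
    )
    return DensityVolume(data, voxel)


def angular_difference_deg(euler_a, euler_b) -> float:
    """Geodesic angle between two orientations, in degrees."""
    from scipy.spatial.transform import Rotation

    Ra = euler_to_matrix(euler_a)
    Rb = euler_to_matrix(euler_b)
    return float(np.degrees(np.linalg.norm(Rotation.from_matrix(Ra.T @ Rb).as_rotvec())))


def align_iterate(
    subtomos: list[DensityVolume],
    particles: ParticleSet,
    template: DensityVolume | None = None,
    config: AlignmentConfig = None,
) -> tuple[ParticleSet, SubtomogramAverage]:
    """Iteratively refine particle poses against an evolving average.

    Per iteration and per particle the best pose over the current
    cone/azimuth/shift grid is taken; a new coverage-weighted average is then
    built from the best poses.  The schedule advances each iteration; once
    exhausted, iterations repeat the finest stage until the median orientation
    change drops below the current angular step or ``max_iterations`` is
    reached.  With ``gold_standard`` half sets are refined against their own
    averages throughout.
    """
    if config is None:
        config = AlignmentConfig(box_edge_vox=subtomos[0].data.shape[0])
    if len(subtomos) == 0 or len(particles) != len(subtomos):
        raise ValueError("need one particle per subtomogram, non-empty")
    shape = subtomos[0].data.shape
    if template is not None and template.data.shape != shape:
        raise ValueError("template box does not match subtomogram box")
    voxel = subtomos[0].voxel_size_nm

    particles = particles.assign_half_sets() if any(p.half_set is None for p in particles) else particles
    work = [p.with_pose() for p in particles]  # mutable copies
    for p in work:
        _set_shift(p, np.zeros(3))

    arrs = [s.data.astype(np.float64) - s.data.mean() for s in subtomos]
    apod = _apodization_window(shape[0])
    arrs = [a * apod for a in arrs]

    wedge_shifted = None
    if config.wedge_compensation:
        wedge_shifted = np.fft.fftshift(missing_wedge_mask(shape, config.tilt).astype(np.float32))
    lowpass_half = _lowpass_filter(shape, voxel, config.lowpass_nm)[..., : shape[-1] // 2 + 1]

    halves = {"A": [i for i, p in enumerate(work) if p.half_set == "A"],
              "B": [i for i, p in enumerate(work) if p.half_set == "B"]}
    if config.gold_standard and (not halves["A"] or not halves["B"]):
        raise ValueError("gold-standard refinement requires particles in both half sets")

    if template is None:
        tmpl_all = initial_template(subtomos, particles, config).data.astype(np.float64)
        templates = {"A": tmpl_all, "B": tmpl_all}
    else:
        t = template.data.astype(np.float64) - template.data.mean()
        templates = {"A": t, "B": t}

    n_stages = len(config.cone_halfangle_schedule_deg)
    log = []
    prev_azimuth_full = True
    for it in range(config.max_iterations):
        cone, step = config.stage(it)
        if it == 0:
            # full azimuthal scan (up to the configured range) on the first pass
            az_lo, az_hi, az_step = 0.0, config.azimuth_range_deg - 1e-6, step
        else:
            # thereafter the azimuth, like the axis, stays within the cone
            half_range = min(config.azimuth_range_deg / 2.0, max(cone, step))
            az_lo, az_hi, az_step = -half_range, half_range, step
        perts = _perturbation_rotations(cone, step, az_lo, az_hi, az_step)

        nxh = shape[-1] // 2 + 1
        changes, scores = [], []
        tmpl_fft_cache = {}
        for half in ("A", "B"):
            idxs = halves[half]
            if not idxs:
                continue
            tmpl = templates[half]
            key = id(tmpl)
            if key not in tmpl_fft_cache:
                tmpl_fft_cache[key] = [
                    sfft.rfftn(_rotate_array(tmpl, R).astype(np.float32)) for R in perts
                ]
            tmpl_ffts = tmpl_fft_cache[key]
            for i in idxs:
                p = work[i]
                R_cur = euler_to_matrix(p.euler_zyz_deg)
                rot_sub = _rotate_array(arrs[i], R_cur.T)
                if wedge_shifted is not None:
                    w = (
                        _rotate_wedge(wedge_shifted, R_cur.T)[..., :nxh].astype(np.float32)
                        * lowpass_half
                    )
                else:
                    w = lowpass_half.copy()
                w[0, 0, 0] = 0.0
                score, pi, shift_ref = search_best_pose(
                    rot_sub, tmpl, perts, w, config.shift_limit_vox, template_ffts=tmpl_ffts
                )
                R_new = R_cur @ perts[pi]
                new_euler = matrix_to_euler(R_new)
                changes.append(angular_difference_deg(p.euler_zyz_deg, new_euler))
                scores.append(score)
                # shift found in the reference frame; carry back to tomogram frame
                d_ref_xyz = shift_ref[::-1]
                d_tomo_xyz = R_cur @ d_ref_xyz
                new_shift = d_tomo_xyz[::-1]
                if np.linalg.norm(new_shift) > config.shift_limit_vox + 1e-6:
                    new_shift *= config.shift_limit_vox / np.linalg.norm(new_shift)
                p.euler_zyz_deg = new_euler
                p.score = float(np.clip(score, -1.0, 1.0))
                _set_shift(p, new_shift)

        for half in ("A", "B"):
            if halves[half]:
                templates[half] = _accumulate_average(
                    arrs, work, halves[half], shape, voxel, wedge_shifted, config.lowpass_nm
                ).astype(np.float64)
        if not config.gold_standard:
            combined = _accumulate_average(
                arrs, work, range(len(work)), shape, voxel, wedge_shifted, config.lowpass_nm
            ).astype(np.float64)
            templates = {"A": combined, "B": combined}

        median_change = float(np.median(changes))
        log.append(
            {
                "iteration": it + 1,
                "cone_deg": cone,
                "step_deg": step,
                "n_poses": len(perts),
                "median_change_deg": median_change,
                "mean_score": float(np.mean(scores)),
            }
        )
        if it >= n_stages - 1 and median_change < step:
            break

    # final maps (no low-pass so FSC measures the true half-map agreement)
    half_maps = {}
    for half in ("A", "B"):
        data = _accumulate_average(arrs, work, halves[half], shape, voxel, wedge_shifted, None)
        half_maps[half] = DensityVolume(data, voxel)
    full = _accumulate_average(arrs, work, range(len(work)), shape, voxel, wedge_shifted, None)

    out_particles = []
    for p in work:
        shift = _current_shift(p)
        out_particles.append(
            Particle(
                position_vox=p.position_vox + shift,
                euler_zyz_deg=p.euler_zyz_deg,
                score=p.score,
                half_set=p.half_set,
                true_euler_zyz_deg=p.true_euler_zyz_deg,
            )
        )
    pset = ParticleSet(out_particles, particles.source_volume, list(particles.provenance))
    pset.log(
        f"align_iterate: {len(log)} iterations, final median change "
        f"{log[-1]['median_change_deg']:.2f} deg, mean score {log[-1]['mean_score']:.3f}"
    )
    avg = SubtomogramAverage(
        map=DensityVolume(full, voxel),
        n_particles=len(work),
        half_map_A=half_maps["A"],
        half_map_B=half_maps["B"],
        config_used=config,
        iteration_log=log,
    )
    return pset, avg
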