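"""Density-volume and particle-table I/O plus the package-wide geometry conventions.

Conventions (single source of truth, used by every other module):

* Grid arrays are indexed ``[z, y, x]`` with 0-based voxel indices.
* Physical coordinates are in nanometres; voxels are isotropic.
* Orientations are intrinsic Z-Y-Z Euler triples in degrees, normalized to
  ``[0, 360) x [0, 180] x [0, 360)``.  The rotation maps reference-frame
  vectors into the tomogram frame: ``v_tomo = R(euler) @ v_ref`` with vectors
  in ``(x, y, z)`` component order.

Volumes are stored on disk as MRC2014 maps (via gemmi, which writes the
standard x-fastest layout); particle tables are tab-separated text with named
columns so fixtures stay diffable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityVolume",
    "Particle",
    "ParticleSet",
    "read_density_map",
    "write_density_map",
    "read_particles",
    "write_particles",
    "euler_to_matrix",
    "matrix_to_euler",
    "normalize_euler",
]

#: nm -> Angstrom scale used in MRC cell headers.
_NM_TO_ANGSTROM = 10.0

#: Columns a particle table must provide.
REQUIRED_PARTICLE_COLUMNS = (
    "pos_z_vox",
    "pos_y_vox",
    "pos_x_vox",
    "euler_z1_deg",
    "euler_y_deg",
    "euler_z2_deg",
)

OPTIONAL_PARTICLE_COLUMNS = (
    "score",
    "half_set",
    "true_euler_z1_deg",
    "true_euler_y_deg",
    "true_euler_z2_deg",
)


# ---------------------------------------------------------------------------
# Euler-angle helpers
# ---------------------------------------------------------------------------

def normalize_euler(euler_zyz_deg) -> np.ndarray:
    """Map an intrinsic Z-Y-Z triple onto [0,360) x [0,180] x [0,360).

    Uses the rotation group rather than naive modular arithmetic so the
    returned triple always represents the same rotation.
    """
    import warnings

    rot = Rotation.from_euler("ZYZ", np.asarray(euler_zyz_deg, dtype=float), degrees=True)
    with warnings.catch_warnings():
        # at b = 0 or 180 the decomposition is degenerate; scipy's canonical
        # choice (third angle zero) is exactly what we want
        warnings.simplefilter("ignore", UserWarning)
        a, b, c = rot.as_euler("ZYZ", degrees=True)
    # scipy returns a, c in (-180, 180] and b in [0, 180]; guard the float
    # edge case where x % 360.0 returns 360.0 for tiny negative x
    a = a % 360.0
    c = c % 360.0
    return np.array([0.0 if a >= 360.0 else a, b, 0.0 if c >= 360.0 else c])


def euler_to_matrix(euler_zyz_deg) -> np.ndarray:
    """3x3 rotation matrix (x,y,z component order) for an intrinsic Z-Y-Z triple."""
    return Rotation.from_euler("ZYZ", np.asarray(euler_zyz_deg, dtype=float), degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix`, normalized to the package ranges."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ang = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return normalize_euler(ang)


# ---------------------------------------------------------------------------
# DensityVolume
# ---------------------------------------------------------------------------

@dataclass
class DensityVolume:
    """A 3D scalar density grid with physical voxel size.

    Parameters
    ----------
    data
        Density values indexed ``[z, y, x]`` (arbitrary units).
    voxel_size_nm
        Isotropic voxel edge length in nanometres; must be positive.
    origin_nm
        Physical position of voxel (0, 0, 0), in nm, stored ``(z, y, x)``.
    """

    data: np.ndarray
    voxel_size_nm: float
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"density grid must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size_nm > 0:
            raise ValueError(f"voxel_size_nm must be positive, got {self.voxel_size_nm}")
        self.origin_nm = np.asarray(self.origin_nm, dtype=float)
        if self.origin_nm.shape != (3,):
            raise ValueError("origin_nm must be a 3-vector (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_nm(self) -> np.ndarray:
        """Physical edge lengths (z, y, x) in nm."""
        return np.array(self.data.shape) * self.voxel_size_nm

    def vox_to_nm(self, pos_vox) -> np.ndarray:
        """Voxel coordinates (z,y,x) -> physical nm coordinates (z,y,x)."""
        return np.asarray(pos_vox, dtype=float) * self.voxel_size_nm + self.origin_nm

    def nm_to_vox(self, pos_nm) -> np.ndarray:
        """Physical nm coordinates (z,y,x) -> voxel coordinates (z,y,x)."""
        return (np.asarray(pos_nm, dtype=float) - self.origin_nm) / self.voxel_size_nm

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.data.copy(), self.voxel_size_nm, self.origin_nm.copy())


def read_density_map(path) -> DensityVolume:
    """Read an MRC2014/CCP4 density map.

    Voxel size is taken from the header cell parameters; the grid is returned
    in the package's z,y,x axis order.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"density map not found: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"not a parseable MRC/CCP4 map: {path}: {exc}") from exc
    grid = ccp4.grid
    arr = np.array(grid.array, dtype=np.float32)  # (x, y, z) fastest-last
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))  # -> (z, y, x)
    nx = grid.nu
    spacing_ang = grid.unit_cell.a / nx if nx else 0.0
    if spacing_ang <= 0:
        raise ValueError(f"malformed header: non-positive cell/grid in {path}")
    origin_ang = np.array(
        [ccp4.header_float(52), ccp4.header_float(51), ccp4.header_float(50)]
    )  # ORIGIN words, (z, y, x)
    return DensityVolume(
        data,
        voxel_size_nm=spacing_ang / _NM_TO_ANGSTROM,
        origin_nm=origin_ang / _NM_TO_ANGSTROM,
    )


def write_density_map(vol: DensityVolume, path, overwrite: bool = False):
    """Write ``vol`` as a standard MRC2014 map (mode 2, x-fastest).

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path} without overwrite=True")
    nz, ny, nx = vol.data.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid.array)[:] = vol.data.transpose(2, 1, 0)
    cell_ang = np.array([nx, ny, nz]) * vol.voxel_size_nm * _NM_TO_ANGSTROM
    grid.set_unit_cell(gemmi.UnitCell(*cell_ang, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    oz, oy, ox = vol.origin_nm * _NM_TO_ANGSTROM
    ccp4.set_header_float(50, float(ox))
    ccp4.set_header_float(51, float(oy))
    ccp4.set_header_float(52, float(oz))
    ccp4.write_ccp4_map(path)
    return path


# ---------------------------------------------------------------------------
# Particles
# ---------------------------------------------------------------------------

@dataclass
class Particle:
    """One picked crown: position, orientation, matching score and half-set label.

    ``position_vox`` is (z, y, x) in 0-based voxel coordinates of the source
    tomogram.  ``true_euler_zyz_deg`` carries generator ground truth for
    synthetic particles and is never touched by refinement.
    """

    position_vox: np.ndarray
    euler_zyz_deg: np.ndarray
    score: float | None = None
    half_set: str | None = None
    true_euler_zyz_deg: np.ndarray | None = None

    def __post_init__(self):
        self.position_vox = np.asarray(self.position_vox, dtype=float)
        self.euler_zyz_deg = normalize_euler(self.euler_zyz_deg)
        if self.score is not None and not (-1.0 - 1e-9 <= self.score <= 1.0 + 1e-9):
            raise ValueError(f"score must lie in [-1, 1], got {self.score}")
        if self.half_set is not None and self.half_set not in ("A", "B"):
            raise ValueError(f"half_set must be 'A' or 'B', got {self.half_set!r}")
        if self.true_euler_zyz_deg is not None:
            self.true_euler_zyz_deg = normalize_euler(self.true_euler_zyz_deg)

    def with_pose(self, position_vox=None, euler_zyz_deg=None, score=None) -> "Particle":
        """Copy with updated pose; half-set label and ground truth are immutable."""
        return Particle(
            position_vox=self.position_vox if position_vox is None else position_vox,
            euler_zyz_deg=self.euler_zyz_deg if euler_zyz_deg is None else euler_zyz_deg,
            score=self.score if score is None else score,
            half_set=self.half_set,
            true_euler_zyz_deg=None if self.true_euler_zyz_deg is None else self.true_euler_zyz_deg.copy(),
        )


@dataclass
class ParticleSet:
    """Ordered collection of particles with a provenance log.

    Alignment operations preserve the particle count; any exclusion must be
    recorded through :meth:`log`.
    """

    particles: list[Particle]
    source_volume: str = ""
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def __getitem__(self, idx) -> Particle:
        return self.particles[idx]

    def log(self, message: str):
        self.provenance.append(message)

    def assign_half_sets(self) -> "ParticleSet":
        """Assign alternating A/B labels to particles that lack one."""
        out = []
        for i, p in enumerate(self.particles):
            if p.half_set is None:
                p = replace(p, half_set="A" if i % 2 == 0 else "B")
            out.append(p)
        ps = ParticleSet(out, self.source_volume, list(self.provenance))
        ps.log("assigned alternating half-set labels")
        return ps

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.particles:
            row = {
                "pos_z_vox": p.position_vox[0],
                "pos_y_vox": p.position_vox[1],
                "pos_x_vox": p.position_vox[2],
                "euler_z1_deg": p.euler_zyz_deg[0],
                "euler_y_deg": p.euler_zyz_deg[1],
                "euler_z2_deg": p.euler_zyz_deg[2],
                "score": np.nan if p.score is None else p.score,
                "half_set": "" if p.half_set is None else p.half_set,
            }
            if p.true_euler_zyz_deg is not None:
                row["true_euler_z1_deg"] = p.true_euler_zyz_deg[0]
                row["true_euler_y_deg"] = p.true_euler_zyz_deg[1]
                row["true_euler_z2_deg"] = p.true_euler_zyz_deg[2]
            rows.append(row)
        return pd.DataFrame(rows)

    @staticmethod
    def from_dataframe(df: pd.DataFrame, source_volume: str = "") -> "ParticleSet":
        missing = [c for c in REQUIRED_PARTICLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"particle table missing required columns: {missing}")
        for col in REQUIRED_PARTICLE_COLUMNS:
            if not np.issubdtype(np.asarray(df[col]).dtype, np.number):
                raise ValueError(f"particle column {col!r} is not numeric")
        has_truth = all(
            c in df.columns for c in ("true_euler_z1_deg", "true_euler_y_deg", "true_euler_z2_deg")
        )
        particles = []
        for _, row in df.iterrows():
            score = row.get("score", np.nan)
            half = row.get("half_set", "")
            half = None if (pd.isna(half) or half == "") else str(half)
            particles.append(
                Particle(
                    position_vox=[row["pos_z_vox"], row["pos_y_vox"], row["pos_x_vox"]],
                    euler_zyz_deg=[row["euler_z1_deg"], row["euler_y_deg"], row["euler_z2_deg"]],
                    score=None if pd.isna(score) else float(score),
                    half_set=half,
                    true_euler_zyz_deg=(
                        [row["true_euler_z1_deg"], row["true_euler_y_deg"], row["true_euler_z2_deg"]]
                        if has_truth
                        else None
                    ),
                )
            )
        return ParticleSet(particles, source_volume=source_volume)


def write_particles(pset: ParticleSet, path, overwrite: bool = False):
    """Write a particle set as TSV with a commented convention header."""
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path} without overwrite=True")
    df = pset.to_dataframe()
    with open(path, "w") as fh:
        fh.write("# spherulescope particle table; euler convention: intrinsic ZYZ, degrees;"
                 " positions: 0-based voxels, z,y,x\n")
        if pset.source_volume:
            fh.write(f"# source_volume: {pset.source_volume}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    return path


def read_particles(path) -> ParticleSet:
    """Read a TSV particle table written by :func:`write_particles`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"particle table not found: {path}")
    source = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# source_volume:"):
                source = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    return ParticleSet.from_dataframe(df, source_volume=source)
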