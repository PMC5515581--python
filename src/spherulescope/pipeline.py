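"""End-to-end seeded demonstration pipeline.

One config + one seed reproduces the whole run: phantom generation, iterative
subtomogram alignment, FSC between independently refined half maps, cyclic
symmetry detection, spherule morphometry (spacing + volume mixture), and the
dsRNA packing report.  Every stage writes its artifact (MRC/TSV) next to the
structured JSON report, and the resolved config is saved with the outputs so
a run can be replayed.
"""

from __future__ import annotations

import json
import os
import tomllib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import fsc as fsc_mod
from . import morphometry, packing, symmetry
from .align import AlignmentConfig, align_iterate
from .phantom import (
    CrownSpec,
    SpheruleSpec,
    TiltGeometry,
    make_crown_particle_stack,
    make_spherule_phantom,
    sample_volume_mixture,
)
from .volumes import write_density_map, write_particles

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable description of one demonstration run."""

    seed: int = 7
    # crown stack
    n_particles: int = 100
    snr: float = 0.5
    teeth_count: int = 12
    box_edge_vox: int = 48
    voxel_size_nm: float = 1.0
    tilt_min_deg: float = -60.0
    tilt_max_deg: float = 60.0
    # alignment
    max_iterations: int = 12
    cone_schedule_deg: tuple = (60.0, 30.0, 15.0, 8.0, 5.0)
    step_schedule_deg: tuple = (30.0, 15.0, 8.0, 4.0, 2.5)
    shift_limit_vox: float = 5.0
    lowpass_nm: float = 6.6
    # morphometry stage
    spherule_radius_nm: float = 25.0
    filament_spacing_nm: float = 6.4
    # volume mixture stage (RNA1-replication size classes)
    mixture_means_nm3: tuple = (12_000.0, 108_000.0)
    mixture_sd_frac: float = 0.2
    mixture_weights: tuple = (0.5, 0.5)
    mixture_n: int = 541
    mixture_k_max: int = 5

    @staticmethod
    def from_toml(path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in PipelineConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cone_schedule_deg", "step_schedule_deg", "mixture_means_nm3", "mixture_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return PipelineConfig(**raw)

    def to_toml(self, path):
        with open(path, "w") as fh:
            fh.write("# spherulescope pipeline config (resolved)\n")
            for key, value in asdict(self).items():
                if isinstance(value, (tuple, list)):
                    fh.write(f"{key} = {list(value)}\n")
                elif isinstance(value, str):
                    fh.write(f'{key} = "{value}"\n')
                else:
                    fh.write(f"{key} = {value}\n")
        return path


def run_pipeline(config: PipelineConfig, out_dir, write_artifacts: bool = True) -> dict:
    """Execute all stages in order and return the structured report.

    Identical config + seed gives an identical report.  Any stage failure is
    re-raised annotated with the stage name; artifacts written before the
    failure are preserved.
    """
    os.makedirs(out_dir, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    child = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    report: dict = {"seed": config.seed, "stages": []}
    stage = "config"
    try:
        if write_artifacts:
            config.to_toml(os.path.join(out_dir, "config_resolved.toml"))

        stage = "phantom"
        tilt = TiltGeometry(config.tilt_min_deg, config.tilt_max_deg)
        crown_spec = CrownSpec(teeth_count=config.teeth_count)
        subtomos, particles = make_crown_particle_stack(
            crown_spec,
            n_particles=config.n_particles,
            snr=config.snr,
            tilt=tilt,
            voxel_size_nm=config.voxel_size_nm,
            box_edge_vox=config.box_edge_vox,
            seed=child[0],
        )
        report["stages"].append(stage)

        stage = "align"
        acfg = AlignmentConfig(
            box_edge_vox=config.box_edge_vox,
            cone_halfangle_schedule_deg=config.cone_schedule_deg,
            angular_step_schedule_deg=config.step_schedule_deg,
            shift_limit_vox=config.shift_limit_vox,
            max_iterations=config.max_iterations,
            lowpass_nm=config.lowpass_nm,
            tilt=tilt,
        )
        refined, average = align_iterate(subtomos, particles, config=acfg)
        if write_artifacts:
            write_particles(refined, os.path.join(out_dir, "particles_refined.tsv"), overwrite=True)
            write_density_map(average.map, os.path.join(out_dir, "crown_average.mrc"), overwrite=True)
            write_density_map(average.half_map_A, os.path.join(out_dir, "half_A.mrc"), overwrite=True)
            write_density_map(average.half_map_B, os.path.join(out_dir, "half_B.mrc"), overwrite=True)
        report["alignment"] = {
            "n_particles": average.n_particles,
            "iterations": len(average.iteration_log),
            "final_median_change_deg": average.iteration_log[-1]["median_change_deg"],
            "final_mean_score": average.iteration_log[-1]["mean_score"],
        }
        report["stages"].append(stage)

        stage = "fsc"
        curve = fsc_mod.compute_fsc(average.half_map_A, average.half_map_B)
        res143, nyq143 = fsc_mod.resolution_at_threshold(curve, 0.143)
        res50, nyq50 = fsc_mod.resolution_at_threshold(curve, 0.5)
        if write_artifacts:
            _write_tsv(
                os.path.join(out_dir, "fsc.tsv"),
                ["freq_inv_nm", "fsc", "n_voxels"],
                zip(curve.shell_freq_inv_nm, curve.correlation, curve.n_voxels_per_shell),
            )
        report["fsc"] = {
            "resolution_nm_at_0.143": res143,
            "nyquist_limited_at_0.143": nyq143,
            "resolution_nm_at_0.5": res50,
            "nyquist_limited_at_0.5": nyq50,
            "mask": curve.mask_applied,
        }
        report["stages"].append(stage)

        stage = "symmetry"
        rb, hb = symmetry.crown_band_defaults(crown_spec)
        spectrum = symmetry.crown_spectrum_from_particles(subtomos, refined, rb, hb)
        order, prominence = symmetry.detect_symmetry_order(spectrum)
        if write_artifacts:
            _write_tsv(
                os.path.join(out_dir, "angular_power_spectrum.tsv"),
                ["component", "mean_power"],
                zip(spectrum.component, spectrum.mean_power),
            )
        report["symmetry"] = {
            "order": order,
            "prominence": prominence,
            "n_profiles": spectrum.n_profiles_averaged,
            "radius_band_nm": list(rb),
            "miscentring_power": spectrum.miscentring_power,
        }
        report["stages"].append(stage)

        stage = "morphometry"
        sph_spec = SpheruleSpec(
            radius_nm=config.spherule_radius_nm,
            filament_spacing_nm=config.filament_spacing_nm,
            crown=crown_spec,
        )
        sph_vol, truth = make_spherule_phantom(sph_spec, config.voxel_size_nm, seed=child[1])
        spacing = morphometry.interfilament_spacing(truth.filament_path_nm)
        meas = morphometry.measure_spherule(
            sph_vol, center_guess_nm=truth.center_vox * config.voxel_size_nm,
            search_radius_nm=sph_spec.radius_nm + 6.0,
        )
        report["morphometry"] = {
            "interfilament_spacing_nm": spacing,
            "target_spacing_nm": config.filament_spacing_nm,
            "measured_radius_nm": meas.radius_nm,
            "true_radius_nm": truth.radius_nm,
            "measured_volume_nm3": meas.volume_nm3,
        }
        report["stages"].append(stage)

        stage = "volume_mixture"
        sds = tuple(m * config.mixture_sd_frac for m in config.mixture_means_nm3)
        volumes = sample_volume_mixture(
            config.mixture_means_nm3, sds, config.mixture_weights, config.mixture_n, seed=child[2]
        )
        if write_artifacts:
            _write_tsv(os.path.join(out_dir, "volumes.tsv"), ["volume_nm3"], ((v,) for v in volumes))
        summary = morphometry.summarize_volumes(volumes)
        mixture = morphometry.fit_volume_mixture(volumes, k_range=(1, config.mixture_k_max), seed=child[3])
        report["volume_mixture"] = {
            "n": int(summary["n"]),
            "mean_nm3": summary["mean"],
            "sd_nm3": summary["sd"],
            "k_selected": mixture.k,
            "means_nm3": [float(m) for m in mixture.means_nm3],
            "weights": [float(w) for w in mixture.weights],
            "converged": mixture.converged,
        }
        report["stages"].append(stage)

        stage = "packing"
        model = packing.PackingModel()
        table = packing.packing_report(model)
        if write_artifacts:
            table.to_csv(os.path.join(out_dir, "packing.tsv"), sep="\t", index=False)
        report["packing"] = {
            "reference_density_bp_per_1000nm3": model.ref_density_bp_per_1000nm3,
            "fold_stated": model.stated_fold,
            "fold_from_spacing": model.fold_from_spacing,
            "density_bp_per_1000nm3": model.density_bp_per_1000nm3,
            "density_from_spacing_bp_per_1000nm3": model.density_from_spacing_bp_per_1000nm3,
            "occupied_volumes_nm3": {
                row["template"]: row["occupied_volume_nm3"] for _, row in table.iterrows()
            },
            "immunogold_max_distance_nm": packing.immunogold_max_distance(),
        }
        report["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if write_artifacts:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
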