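"""Config-driven orchestration: validate a YAML run config, execute the
requested analysis stages in dependency order, and write per-stage tables
plus a one-file summary.

The config surfaces every analysis parameter with the library defaults
(0.4 nm surface grid, 0.5 nm hydration shell, |q| <= 0.2 e hydrophobicity
cutoff, 0.14 nm probe); a fixed seed makes a synthetic run byte-identical
between invocations.
"""

from __future__ import annotations

import difflib
import logging
import os
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import density as _density
from . import dynamics as _dynamics
from . import io as _io
from . import structure as _structure
from . import surface as _surface
from . import synth as _synth
from .core import recenter_slab
from .sasa import sasa_series as _sasa_series
from .select import select

log = logging.getLogger("hydralyze")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FileInput(_Strict):
    coords: str
    charges: str
    trajectory: Optional[str] = None


class SynthInput(_Strict):
    kind: Literal["benchmark"] = "benchmark"
    box: tuple[float, float, float] = (6.0, 6.0, 12.0)
    slab_z_range: tuple[float, float] = (1.0, 3.0)
    corrugation_mode: Literal["flat", "two_level", "sinusoid"] = "sinusoid"
    corrugation_amplitude: float = 0.5
    corrugation_wavelength: float = 3.0
    atom_spacing: float = 0.2
    charge_pattern: tuple[float, ...] = (-0.5, 0.3, 0.1, 0.1)
    n_waters: int = 200
    true_D: float = 2.5
    n_frames: int = 200
    dt: float = 2.0


class SurfaceStage(_Strict):
    cell_size: float = 0.4
    sides: tuple[str, ...] = ("up", "down")


class DensityStage(_Strict):
    bin_width: float = 0.1
    symmetrize: bool = True
    selections: tuple[str, ...] = ("membrane", "water")


class SasaStage(_Strict):
    probe: float = 0.14
    n_points: int = 960
    charge_cutoff: float = 0.2
    frames: str = "last:3"


class OrientationStage(_Strict):
    bin_width: float = 0.1
    reference: Literal["grid", "plane"] = "grid"
    plane_z: float = 0.0
    cell_size: float = 0.4


class ResidenceStage(_Strict):
    cutoff: float = 0.5
    gap_tolerance: int = 0
    distribution_bin: float = 2.0


class DiffusionStage(_Strict):
    fit: tuple[float, float] = (0.1, 0.5)
    n_blocks: int = 5
    max_lag: Optional[float] = None
    hydration_layer: bool = False
    shell_cutoff: float = 0.5


class RdfStage(_Strict):
    reference: str = "name OW"
    target: str = "name OW"
    r_max: float = 1.0
    dr: float = 0.01


class SdfStage(_Strict):
    anchors: tuple[int, int, int]
    spacing: float = 0.05
    r_max: float = 0.8


class Stages(_Strict):
    surface: Optional[SurfaceStage] = None
    density: Optional[DensityStage] = None
    sasa: Optional[SasaStage] = None
    orientation: Optional[OrientationStage] = None
    residence: Optional[ResidenceStage] = None
    diffusion: Optional[DiffusionStage] = None
    rdf: Optional[RdfStage] = None
    sdf: Optional[SdfStage] = None

    def enabled(self) -> list[str]:
        return [k for k, v in self.__dict__.items() if v is not None]


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "hydralyze_out"
    input: Optional[FileInput] = None
    synth: Optional[SynthInput] = None
    selections: dict[str, str] = {
        "membrane": "molname MEM",
        "water": "molname SOL",
        "water_oxygen": "molname SOL and name OW",
    }
    frames: str = "all"
    center: bool = False
    stages: Stages = Stages()

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        if (self.input is None) == (self.synth is None):
            raise ValueError("exactly one of 'input' and 'synth' must be given")
        if not self.stages.enabled():
            raise ValueError("no stages enabled; nothing to do")
        for key in ("membrane", "water"):
            if key not in self.selections:
                raise ValueError(f"selections must define {key!r}")
        st = self.stages
        for name, val in [
            ("surface.cell_size", st.surface.cell_size if st.surface else 1),
            ("density.bin_width", st.density.bin_width if st.density else 1),
            ("sasa.probe", st.sasa.probe if st.sasa else 1),
            ("residence.cutoff", st.residence.cutoff if st.residence else 1),
            ("rdf.r_max", st.rdf.r_max if st.rdf else 1),
        ]:
            if not val > 0:
                raise ValueError(f"{name} must be > 0")
        return self


def _suggest(err: dict) -> str:
    msg = err["msg"]
    loc = ".".join(str(p) for p in err["loc"])
    if err["type"] == "extra_forbidden":
        field = str(err["loc"][-1])
        parent = err["loc"][:-1]
        known: list[str] = []
        model: type[BaseModel] = RunConfig
        try:
            for part in parent:
                ann = model.model_fields[str(part)].annotation
                for cand in getattr(ann, "__args__", (ann,)):
                    if isinstance(cand, type) and issubclass(cand, BaseModel):
                        model = cand
                        break
            known = list(model.model_fields)
        except Exception:
            pass
        close = difflib.get_close_matches(field, known, n=1)
        hint = f" (did you mean {close[0]!r}?)" if close else ""
        return f"{loc}: unknown key{hint}"
    return f"{loc}: {msg}"


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def validate(path: str | os.PathLike) -> list[str]:
    """Validate a config file; returns a list of violations (empty = ok)."""
    try:
        load_config(path)
    except ValidationError as exc:
        return [_suggest(e) for e in exc.errors()]
    except (OSError, yaml.YAMLError, ValueError) as exc:
        return [str(exc)]
    return []


def _build_system(config: RunConfig):
    if config.input is not None:
        topology = _io.read_topology(config.input.coords, config.input.charges)
        traj_path = config.input.trajectory or config.input.coords
        traj = _io.read_trajectory(traj_path, topology)
        return topology, traj
    s = config.synth
    assert s is not None
    slab_top, slab_traj = _synth.make_slab(
        _synth.SlabSpec(
            box=s.box,
            slab_z_range=s.slab_z_range,
            corrugation=_synth.Corrugation(
                mode=s.corrugation_mode,
                amplitude=s.corrugation_amplitude,
                wavelength=s.corrugation_wavelength,
            ),
            atom_spacing=s.atom_spacing,
            charge_pattern=s.charge_pattern,
            n_frames=s.n_frames,
            dt=s.dt,
        ),
        seed=config.seed,
    )
    sol_top, sol_traj = _synth.make_oriented_waters(
        _synth.SolventSpec(
            n_waters=s.n_waters, true_D=s.true_D, dt=s.dt, n_frames=s.n_frames
        ),
        box=s.box,
        seed=config.seed + 1,
        z_range=(s.slab_z_range[1] + s.corrugation_amplitude + 0.1, s.box[2] - 0.1),
    )
    return _synth.merge_systems((slab_top, slab_traj), (sol_top, sol_traj))


def _fmt(value: float) -> str:
    return f"{value:.8g}"


def run(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the summary mapping.

    Writes per-stage TSVs plus ``summary.tsv`` into ``output_dir``; any
    stage failure raises :class:`PipelineError` naming the stage, with
    already-written outputs left in place.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.output_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict[str, float] = {}
    try:
        log.info("seed=%d stages=%s", config.seed, ",".join(config.stages.enabled()))
        topology, traj = _build_system(config)
        log.info("system: %d atoms, %d frames", topology.n_atoms, traj.n_frames)
        membrane = select(topology, config.selections["membrane"])
        water = select(topology, config.selections["water"])
        water_o = select(
            topology,
            config.selections.get("water_oxygen", config.selections["water"]),
        )
        if config.center:
            traj = recenter_slab(traj, membrane.atom_ids)
        common = {"seed": config.seed, "frames": config.frames}

        st = config.stages
        stage = "surface"
        grids_up = None
        try:
            if st.surface is not None:
                for side in st.surface.sides:
                    series = _surface.roughness_series(
                        traj, membrane, cell_size=st.surface.cell_size,
                        side=side, frame_range=config.frames,
                    )
                    summary[f"roughness_{side}_mean_nm"] = series["mean"]
                    summary[f"roughness_{side}_sem_nm"] = series["sem"]
                    summary[f"roughness_{side}_sd_nm"] = series["sd"]
                    grids = [
                        _surface.extract_surface(
                            traj, membrane, frame=int(f),
                            cell_size=st.surface.cell_size, side=side,
                        )
                        for f in series["frames"]
                    ]
                    if side == "up":
                        grids_up = grids
                    _io.write_table(
                        _surface.contour_map(grids),
                        os.path.join(config.output_dir, f"contour_{side}.tsv"),
                        params={**common, "cell_size_nm": st.surface.cell_size, "side": side},
                    )
                log.info("surface: R_up = %.4g nm", summary.get("roughness_up_mean_nm", np.nan))

            stage = "density"
            if st.density is not None:
                for key in st.density.selections:
                    sel = select(topology, config.selections[key])
                    prof = _density.density_profile(
                        traj, topology, sel, bin_width=st.density.bin_width,
                        frame_range=config.frames,
                    )
                    if st.density.symmetrize:
                        center = _density.membrane_center(
                            traj, topology, membrane, frame_range=config.frames
                        )
                        prof = _density.symmetrize(prof, center)
                    _io.write_table(
                        prof,
                        os.path.join(config.output_dir, f"density_{key}.tsv"),
                        params=common,
                    )

            stage = "sasa"
            if st.sasa is not None:
                res = _sasa_series(
                    traj, topology, membrane, frame_range=st.sasa.frames,
                    probe=st.sasa.probe, n_points=st.sasa.n_points,
                    cutoff=st.sasa.charge_cutoff,
                )
                summary["sasa_total_nm2"] = res["total_mean"]
                summary["sasa_hydrophilic_nm2"] = res["hydrophilic_mean"]
                summary["sasa_hydrophobic_nm2"] = res["hydrophobic_mean"]
                summary["hydrophilic_fraction"] = res["hydrophilic_fraction"]
                log.info("sasa: hydrophilic fraction %.3f", res["hydrophilic_fraction"])

            stage = "orientation"
            if st.orientation is not None:
                if st.orientation.reference == "grid":
                    frames_idx = traj.frame_slice(
                        _io_frame_range(config.frames, traj.n_frames)
                    )
                    ref = [
                        _surface.extract_surface(
                            traj, membrane, frame=int(f),
                            cell_size=st.orientation.cell_size, side="up",
                        )
                        for f in frames_idx
                    ]
                else:
                    ref = st.orientation.plane_z
                prof = _structure.orientation_profile(
                    traj, topology, water, ref,
                    bin_width=st.orientation.bin_width, frame_range=config.frames,
                )
                _io.write_table(
                    prof, os.path.join(config.output_dir, "orientation.tsv"), params=common
                )

            stage = "residence"
            occ = None
            if st.residence is not None:
                occ = _dynamics.shell_occupancy(
                    traj, water_o, membrane, cutoff=st.residence.cutoff,
                    frame_range=config.frames,
                )
                res = _dynamics.residence_times(occ, gap_tolerance=st.residence.gap_tolerance)
                summary["mean_residence_ps"] = res.mean_residence
                summary["residence_events"] = float(len(res.events))
                summary["residence_censored"] = float(res.censored_count)
                _io.write_table(
                    _dynamics.residence_distribution(res, st.residence.distribution_bin),
                    os.path.join(config.output_dir, "residence_distribution.tsv"),
                    params={**common, "cutoff_nm": st.residence.cutoff,
                            "gap_tolerance": st.residence.gap_tolerance},
                )
                log.info("residence: mean %.4g ps over %d events",
                         res.mean_residence, len(res.events))

            stage = "diffusion"
            if st.diffusion is not None:
                occ_arg = None
                if st.diffusion.hydration_layer:
                    occ_arg = occ if occ is not None else _dynamics.shell_occupancy(
                        traj, water_o, membrane, cutoff=st.diffusion.shell_cutoff,
                        frame_range=config.frames,
                    )
                curve = _dynamics.msd(
                    traj, water_o, max_lag=st.diffusion.max_lag,
                    occupancy=occ_arg, n_blocks=st.diffusion.n_blocks,
                )
                dres = _dynamics.diffusion_coefficient(curve, fit_window=st.diffusion.fit)
                summary["D_1e-5_cm2_s"] = dres.D
                summary["D_uncertainty"] = dres.uncertainty
                summary["msd_fit_r2"] = dres.r_squared
                _io.write_table(curve, os.path.join(config.output_dir, "msd.tsv"), params=common)
                log.info("diffusion: D = %.4g (+/- %.2g) x1e-5 cm^2/s", dres.D, dres.uncertainty)

            stage = "rdf"
            if st.rdf is not None:
                ref_sel = select(topology, st.rdf.reference)
                tgt_sel = select(topology, st.rdf.target)
                rres = _structure.rdf(
                    traj, topology, ref_sel, tgt_sel,
                    r_max=st.rdf.r_max, dr=st.rdf.dr, frame_range=config.frames,
                )
                _io.write_table(rres, os.path.join(config.output_dir, "rdf.tsv"), params=common)
                fm = rres.first_minimum()
                if fm is not None:
                    summary["rdf_first_minimum_nm"] = fm
                    summary["coordination_at_first_min"] = rres.coordination_number(fm)

            stage = "sdf"
            if st.sdf is not None:
                grid = _structure.sdf(
                    traj, topology, st.sdf.anchors, water,
                    spacing=st.sdf.spacing, r_max=st.sdf.r_max, frame_range=config.frames,
                )
                _io.write_dx(
                    os.path.join(config.output_dir, "sdf.dx"),
                    grid.values, grid.origin, (grid.spacing,) * 3,
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

        lines = ["# hydralyze summary", f"# seed = {config.seed}", "quantity\tvalue"]
        for key in sorted(summary):
            lines.append(f"{key}\t{_fmt(summary[key])}")
        with open(os.path.join(config.output_dir, "summary.tsv"), "w") as fh:
            fh.write("\n".join(lines) + "\n")
        log.info("summary written to %s", os.path.join(config.output_dir, "summary.tsv"))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _io_frame_range(spec: str, n_frames: int):
    from .core import parse_frame_range

    return parse_frame_range(spec, n_frames)
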