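"""End-to-end pipeline: surrogate dynamics → FEPs → committor → TSE geometry.

A :class:`PipelineConfig` (YAML-serializable, lossless round trip)
drives the stages in order:

1. ``msmd`` — forward/backward steering, Jarzynski estimates, the
   bidirectional splice, and the barrier summary;
2. ``umbrella`` — window ladder and WHAM reconstruction;
3. ``committor`` — grid commitment analysis and TSE extraction;
4. ``geometry`` — TSE members rendered as phosphoryl-transfer frames,
   superposed; ensemble width and PCA.

Stages without a config section are skipped (the pipeline stops after
the stages that are configured).  Every stochastic stage derives its
seed deterministically from the global seed, so a (config, seed) pair
reproduces byte-identical outputs.  All output tables carry a
provenance sidecar (config hash, package version, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .committor import BasinDefinition, committor_curve, define_tse, grid_committor_study
from .fep import SummaryError, barrier_summary, combine_bidirectional, jarzynski_estimate
from .frameio import write_xyz
from .geometry import kabsch_superpose, pca_tse, tse_width
from .msmd import SteeringProtocol, run_msmd
from .potentials import PotentialSpec
from .ptframes import make_pt_frames
from .tables import (
    write_committor_curve,
    write_fep,
    write_shot_log,
    write_windows,
    write_work_profiles,
)
from .umbrella import run_umbrella
from .wham import wham_solve

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    potential: Dict
    seed: int = 0
    units_mode: str = "reduced"
    output_dir: str = "pipeline_out"
    msmd: Optional[Dict] = None
    umbrella: Optional[Dict] = None
    committor: Optional[Dict] = None
    geometry: Optional[Dict] = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _stage_seeds(children, index: int, n: int) -> List[int]:
    child = children[index]
    return (child.generate_state(n, dtype=np.uint64) % (2**31)).astype(int).tolist()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the configured stages; returns the summary dictionary.

    A stage failure raises :class:`PipelineStageError` naming the stage;
    outputs of completed stages remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pot = dict(config.potential)
    pot.setdefault("units_mode", config.units_mode)
    spec = PotentialSpec(**pot)
    root = np.random.SeedSequence(int(config.seed))
    children = root.spawn(5)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "ptse_version": __version__,
    }
    summary: Dict = {"stages": [], "provenance": provenance}
    temperature = spec.temperature
    kT = spec.kT

    combined = None
    if config.msmd is not None:
        try:
            m = dict(config.msmd)
            dt = m.pop("dt", 2.5e-4)
            friction = m.pop("friction", 1.0)
            equil = m.pop("equilibration_steps", 2000)
            scheme = m.pop("scheme", "overdamped")
            n_grid = m.pop("n_grid", 201)
            m.setdefault("temperature", temperature)
            proto_f = SteeringProtocol(direction="forward", **m)
            proto_b = proto_f.reversed()
            n = proto_f.n_replicates
            seeds_f = _stage_seeds(children, 0, n)
            seeds_b = _stage_seeds(children, 1, n)
            prof_f = run_msmd(spec, proto_f, seeds_f, equil, dt, friction, scheme, n_grid)
            prof_b = run_msmd(spec, proto_b, seeds_b, equil, dt, friction, scheme, n_grid)
            fep_f = jarzynski_estimate(prof_f, temperature, seed=seeds_f[0],
                                       units_mode=spec.units_mode)
            fep_b = jarzynski_estimate(prof_b, temperature, seed=seeds_b[0],
                                       units_mode=spec.units_mode)
            combined = combine_bidirectional(fep_f, fep_b)
            write_work_profiles(out / "work_forward.tsv", prof_f, dict(provenance))
            write_work_profiles(out / "work_backward.tsv", prof_b, dict(provenance))
            write_fep(out / "fep_forward.tsv", fep_f, dict(provenance))
            write_fep(out / "fep_backward.tsv", fep_b, dict(provenance))
            write_fep(out / "fep_combined.tsv", combined, dict(provenance))
            stage = {"name": "msmd", "junction_gap": combined.info["junction_gap"]}
            try:
                bs = barrier_summary(combined, min_prominence=0.25 * kT)
                stage["barriers"] = dataclasses.asdict(bs)
            except SummaryError as e:
                stage["barriers"] = None
                stage["barrier_error"] = str(e)
            summary["stages"].append(stage)
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001 - re-raised with stage name
            raise PipelineStageError("msmd", e) from e

    if config.umbrella is not None:
        try:
            u = dict(config.umbrella)
            centers = np.arange(u.pop("start"), u.pop("stop") + 1e-12, u.pop("spacing"))
            seeds_u = _stage_seeds(children, 2, len(centers))
            bin_width = u.pop("bin_width", 0.02)
            tolerance = u.pop("tolerance", 1e-6)
            max_iterations = u.pop("max_iterations", 100_000)
            windows = run_umbrella(spec, centers, seeds=seeds_u, **u)
            sol = wham_solve(windows, temperature, bin_width=bin_width,
                             tolerance=tolerance, max_iterations=max_iterations,
                             units_mode=spec.units_mode)
            write_windows(out / "umbrella", windows)
            write_fep(out / "fep_wham.tsv", sol.profile, dict(provenance))
            summary["stages"].append({
                "name": "umbrella",
                "wham_converged": bool(sol.converged),
                "wham_iterations": int(sol.iterations),
            })
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("umbrella", e) from e

    tse = None
    if config.committor is not None:
        try:
            c = dict(config.committor)
            grid = np.arange(c["grid_start"], c["grid_stop"] + 1e-12, c["grid_spacing"])
            x1, x2 = sorted(spec.well_positions)
            basin = BasinDefinition(
                xi_reactant=c.get("xi_reactant", x1),
                xi_product=c.get("xi_product", x2),
                max_steps=c.get("max_steps", 1_000_000),
            )
            seeds_c = _stage_seeds(children, 3, 1)
            configs, records = grid_committor_study(
                spec,
                grid,
                per_point=c.get("per_point", 20),
                n_shots=c.get("n_shots", 10),
                basin=basin,
                temperature=temperature,
                seed=seeds_c[0],
                restraint_force_constant=c.get("force_constant", 300.0),
                equil_time=c.get("equil_time", 5.0),
                dt=c.get("dt", 5e-4),
                friction=c.get("friction", 1.0),
                scheme=c.get("scheme", "overdamped"),
            )
            curve = committor_curve(records)
            band = tuple(c.get("band", (0.4, 0.6)))
            tse = define_tse(curve, configs, band)
            write_shot_log(out / "shot_log.tsv", records, dict(provenance))
            write_committor_curve(out / "committor_curve.tsv", curve, dict(provenance))
            (out / "tse.yaml").write_text(yaml.safe_dump({
                "band": list(band),
                "n_members": len(tse.members),
                "rc_range": list(tse.rc_range),
                "width": tse.width,
            }))
            summary["stages"].append({
                "name": "committor",
                "n_members": len(tse.members),
                "tse_rc_range": list(tse.rc_range),
                "tse_width": tse.width,
            })
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("committor", e) from e

    if config.geometry is not None and tse is not None and len(tse.members) >= 2:
        try:
            g = dict(config.geometry)
            seeds_g = _stage_seeds(children, 4, 1)
            frames = make_pt_frames(
                tse.member_rc,
                donor_acceptor_distance=g.get("donor_acceptor_distance", 4.5),
                pyramidalization=g.get("pyramidalization", 0.0),
                include_mg=g.get("include_mg", True),
                jitter_sd=g.get("jitter_sd", 0.02),
                seed=seeds_g[0],
            )
            align_roles = g.get("align_roles", ["O_leaving", "O_attacking", "Mg"])
            aligned, rmsd = kabsch_superpose(frames, align_roles)
            mean_disp, sd_disp = tse_width(aligned)
            pca_roles = g.get("pca_roles", ["P_T", "O_nb1", "O_nb2", "O_nb3"])
            pca = pca_tse(aligned, pca_roles)
            write_xyz(out / "tse_frames.xyz", aligned)
            summary["stages"].append({
                "name": "geometry",
                "p_width_mean": mean_disp,
                "p_width_sd": sd_disp,
                "pca_top_eigenvalue_fraction": float(
                    pca.eigenvalues[0] / max(pca.eigenvalues.sum(), 1e-30)
                ),
                "mean_alignment_rmsd": float(np.mean(rmsd)),
            })
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("geometry", e) from e

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(config.to_yaml())
    return summary
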