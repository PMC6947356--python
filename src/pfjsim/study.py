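"""End-to-end study: 7 ligament configurations x 5 flexion angles.

Composes pose -> baseline seating -> element assembly -> incremental
pretension equilibrium -> baseline-subtracted pressures, and assembles the
per-case table of maximum relative contact pressure and maximum MPFL/LR
stress, plus technique comparisons and seeded cohort sensitivity runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._vtk import write_polydata
from .config import Config
from .contact import (ContactParams, baseline_state, max_pressure,
                      relative_pressure, solve_equilibrium)
from .geometry import JointParams, build_joint, pose_at_flexion
from .ligaments import ReconstructionSpec, build_elements

logger = logging.getLogger(__name__)

_TENSION_EPS = 1e-9  # N; below this a graft counts as slack


@dataclass(frozen=True)
class CaseResult:
    """One (technique, graft, angle) outcome."""

    spec: ReconstructionSpec
    angle: float
    max_relative_pressure: float  # MPa
    max_mpfl_stress: float        # MPa
    max_lr_stress: float          # MPa
    graft_tensioned: bool
    converged: bool
    error: str | None = None


@dataclass
class StudyTable:
    rows: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.spec.label, r.angle) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (spec, angle) rows in study table")

    def row(self, technique: str, graft: str, angle: float) -> CaseResult:
        for r in self.rows:
            if (r.spec.technique, r.spec.graft, r.angle) == (technique, graft, angle):
                return r
        raise KeyError(f"no row for ({technique}, {graft}, {angle})")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "technique": r.spec.technique,
            "graft": r.spec.graft,
            "angle_deg": r.angle,
            "max_rel_pressure_MPa": r.max_relative_pressure,
            "max_mpfl_stress_MPa": r.max_mpfl_stress,
            "max_lr_stress_MPa": r.max_lr_stress,
            "tensioned": r.graft_tensioned,
            "converged": r.converged,
        } for r in self.rows])

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe().copy()
        for col in ("max_rel_pressure_MPa", "max_mpfl_stress_MPa",
                    "max_lr_stress_MPa"):
            df[col] = df[col].map(lambda v: f"{v:.6g}")
        df.to_csv(path, index=False, lineterminator="\n")


class _CaseRunner:
    """Caches the joint build and per-angle baselines across cases."""

    def __init__(self, config: Config | None = None,
                 joint_params: JointParams | None = None):
        self.config = config or Config()
        params = joint_params or self.config.joint_params()
        self.joint = build_joint(params)
        self.contact: ContactParams = self.config.contact_params()
        self.tissues = self.config.tissue_table()
        self.profiles = self.config.length_profiles()
        self.cross_section = self.config.cross_section()
        self.n_steps = self.config.study.n_steps
        self._baselines: dict = {}

    def posed(self, angle: float):
        return pose_at_flexion(self.joint, angle)

    def baseline(self, angle: float):
        if angle not in self._baselines:
            self._baselines[angle] = baseline_state(self.posed(angle), self.contact)
        return self._baselines[angle]

    def run(self, spec: ReconstructionSpec, angle: float,
            return_artifacts: bool = False):
        ja = self.posed(angle)
        base = self.baseline(angle)
        elements = build_elements(
            spec, ja, tissues=self.tissues, profiles=self.profiles,
            cross_section=self.cross_section, extra_pose=base.extra)
        sol = solve_equilibrium(ja, elements, self.contact,
                                n_steps=self.n_steps, baseline=base)
        rel = relative_pressure(sol.pressure_field, base.pressure_field)
        mpfl = [el for el in elements if el.role == "mpfl"]
        lr = [el for el in elements if el.role == "lr"]
        max_mpfl = max(el.stress(sol.element_forces[el.name]) for el in mpfl)
        max_lr = max(el.stress(sol.element_forces[el.name]) for el in lr)
        result = CaseResult(
            spec=spec, angle=float(angle),
            max_relative_pressure=max_pressure(rel),
            max_mpfl_stress=max_mpfl,
            max_lr_stress=max_lr,
            graft_tensioned=any(sol.element_forces[el.name] > _TENSION_EPS
                                for el in mpfl),
            converged=sol.converged,
        )
        if return_artifacts:
            return result, {"solution": sol, "baseline": base, "relative": rel}
        return result


def run_case(spec: ReconstructionSpec, angle: float,
             config: Config | None = None,
             runner: _CaseRunner | None = None,
             return_artifacts: bool = False):
    """Run a single reconstruction case at one flexion angle.

    Solver failures are captured in the result row (``converged=False`` /
    ``error``), never raised, so multi-case studies always complete.
    """
    runner = runner or _CaseRunner(config)
    try:
        return runner.run(spec, angle, return_artifacts=return_artifacts)
    except Exception as exc:  # noqa: BLE001 - per-row fault isolation
        logger.exception("case %s at %s deg failed", spec.label, angle)
        if return_artifacts:
            raise
        return CaseResult(spec=spec, angle=float(angle),
                          max_relative_pressure=np.nan,
                          max_mpfl_stress=np.nan, max_lr_stress=np.nan,
                          graft_tensioned=False, converged=False,
                          error=str(exc))


def run_study(config: Config | None = None,
              joint_params: JointParams | None = None,
              out_dir: str | Path | None = None) -> StudyTable:
    """Run every configured case x angle and assemble the study table."""
    config = config or Config()
    runner = _CaseRunner(config, joint_params=joint_params)
    rows = []
    for tech, graft in config.study.cases:
        spec = ReconstructionSpec(technique=tech, graft=graft)
        for angle in config.study.angles:
            logger.info("running %s at %g deg", spec.label, angle)
            rows.append(run_case(spec, angle, runner=runner))
    table = StudyTable(rows=rows, provenance={
        "config_hash": config.hash(),
        "seed": config.cohort.seed,
        "version": __version__,
    })
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.output.export_csv:
            table.to_csv(out / "study_results.csv")
        (out / "study_summary.json").write_text(json.dumps({
            "provenance": table.provenance,
            "comparisons": compare_techniques(
                table, band=config.study.comparison_band)
            if _has_comparison_rows(table, config) else None,
        }, indent=1, sort_keys=True, default=float))
        if config.output.export_vtk:
            _export_fields(runner, config, out)
    return table


def _has_comparison_rows(table: StudyTable, config: Config) -> bool:
    try:
        compare_techniques(table, band=config.study.comparison_band)
        return True
    except (KeyError, ValueError):
        return False


def _export_fields(runner: _CaseRunner, config: Config, out: Path) -> None:
    for tech, graft in config.study.cases:
        spec = ReconstructionSpec(technique=tech, graft=graft)
        for angle in config.study.angles:
            _, art = runner.run(spec, angle, return_artifacts=True)
            rel = art["relative"]
            mesh = rel.mesh.transformed(art["solution"].patella_pose)
            write_polydata(
                out / f"{tech}_{graft}_{angle:g}.vtk", mesh,
                {"relative_pressure_MPa": rel.pressure})


def compare_techniques(table: StudyTable, band: float = 0.2) -> dict:
    """Qualitative orderings at 0 and 30 degrees.

    Technique-level pressures are represented by the semitendinosus rows
    (the one graft tested with all three reconstructions) and the native
    intact knee.  Returns per-assertion booleans and the underlying values.
    """
    report: dict = {"band": band, "assertions": {}, "values": {}}
    for angle in (0.0, 30.0):
        p_static = table.row("static_anatomic", "semitendinosus", angle).max_relative_pressure
        p_mqtfl = table.row("mqtfl", "semitendinosus", angle).max_relative_pressure
        p_amt = table.row("amt_pulley", "semitendinosus", angle).max_relative_pressure
        p_intact = table.row("intact", "native", angle).max_relative_pressure
        a = report["assertions"]
        a[f"static_gt_mqtfl_{angle:g}"] = bool(p_static > p_mqtfl)
        a[f"mqtfl_gt_amt_{angle:g}"] = bool(p_mqtfl > p_amt)
        a[f"amt_within_band_of_intact_{angle:g}"] = bool(
            abs(p_amt - p_intact) <= band * abs(p_intact))
        report["values"][f"pressures_{angle:g}"] = {
            "static_anatomic": p_static, "mqtfl": p_mqtfl,
            "amt_pulley": p_amt, "intact": p_intact,
        }
    s_amt30 = max(table.row("amt_pulley", g, 30.0).max_mpfl_stress
                  for g in ("semitendinosus", "gracilis"))
    s_int30 = table.row("intact", "native", 30.0).max_mpfl_stress
    report["assertions"]["amt_stress_30_gt_intact"] = bool(s_amt30 > s_int30)
    s_allo = table.row("mqtfl", "tibialis_posterior_allograft", 0.0).max_mpfl_stress
    s_semi = table.row("mqtfl", "semitendinosus", 0.0).max_mpfl_stress
    report["assertions"]["mqtfl_allograft_gt_semitendinosus_0"] = bool(s_allo > s_semi)
    report["values"]["stresses"] = {
        "amt_30": s_amt30, "intact_30": s_int30,
        "mqtfl_allograft_0": s_allo, "mqtfl_semitendinosus_0": s_semi,
    }
    return report


def cohort_study(specs: list, cohort: list, config: Config | None = None,
                 angles: list | None = None) -> pd.DataFrame:
    """Per-case distributions of max pressure/stress across cohort members.

    ``cohort`` is a list of JointParams (see geometry.sample_cohort); the
    returned frame has one row per (technique, graft, angle) with mean and
    sd over members.  Per-member failures propagate as NaN rows and are
    summarized with the rest.
    """
    config = config or Config()
    angles = config.study.angles if angles is None else angles
    records = []
    for i, params in enumerate(cohort):
        runner = _CaseRunner(config, joint_params=params)
        for spec in specs:
            for angle in angles:
                r = run_case(spec, angle, runner=runner)
                records.append({
                    "member": i, "technique": spec.technique,
                    "graft": spec.graft, "angle_deg": angle,
                    "max_rel_pressure_MPa": r.max_relative_pressure,
                    "max_mpfl_stress_MPa": r.max_mpfl_stress,
                    "max_lr_stress_MPa": r.max_lr_stress,
                })
    df = pd.DataFrame(records)
    return df.groupby(["technique", "graft", "angle_deg"]).agg(
        pressure_mean=("max_rel_pressure_MPa", "mean"),
        pressure_sd=("max_rel_pressure_MPa", "std"),
        mpfl_stress_mean=("max_mpfl_stress_MPa", "mean"),
        mpfl_stress_sd=("max_mpfl_stress_MPa", "std"),
        lr_stress_mean=("max_lr_stress_MPa", "mean"),
        lr_stress_sd=("max_lr_stress_MPa", "std"),
        n=("member", "count"),
    ).reset_index()
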