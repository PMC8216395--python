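"""Simulation orchestration.

Each integration step composes the model's mechanisms in a fixed
order, so forces always act on the freshest field and polarity state:

1. morphogen solve (quasi-static, per cadence)
2. polarity update (per cadence)
3. vertex forces (tissue energy + tip chemotaxis) and forward Euler
4. corridor enforcement (endo-BC)
5. rearrangement sweep, divisions (lumen-triggered first, then timed
   epithelial, then shape-triggered stalk), lumen growth, branch
   addition, peripheral/central reclassification (per event cadence)

Identical configuration and seed give a bit-identical event log and
statistics trajectory.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .boundaries import (
    EndoBoundary,
    enforce_corridors,
    epithelial_only_vertices,
    register_endo_boundary,
)
from .config import RunConfig
from .energy import ForceEvaluator, euler_step
from .ic import InitialCondition, SyntheticICParams, synthesize_e13_ic
from .mesh import CellType, Mesh
from .polarity import (
    check_polarised_division,
    create_lumen,
    grow_lumina,
    update_polarity,
)
from .populations import (
    add_endothelial_branch,
    advance_cycles_and_divide,
    classify_peripherality,
    grow_target_areas,
    stalk_divide_if_elongated,
)
from .rearrange import rearrangement_sweep, resolve_interpenetrations
from .signalling import MorphogenParams, solve_vegf_field, tip_motile_forces
from .stats import SummaryStats, compute_summary_stats

__all__ = ["Simulation", "RunResult", "run"]


@dataclass
class RunResult:
    mesh: Mesh
    stats: pd.DataFrame
    events: List[dict]
    boundaries: List[EndoBoundary]
    first_lumen_time: Optional[float]
    config: RunConfig


class Simulation:
    """Stateful driver for one run."""

    def __init__(self, config: RunConfig, ic: Optional[InitialCondition] = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        if ic is None:
            ic = synthesize_e13_ic(
                n_epithelial=config.n_epithelial,
                rng=self.rng,
                params=config.ic,
                prolif=config.prolif,
            )
        self.ic = ic
        self.mesh = ic.mesh
        self.boundaries: List[EndoBoundary] = []
        if config.corridors_enabled:
            for sid in ic.stalk_ids:
                try:
                    self.boundaries.append(
                        register_endo_boundary(self.mesh, sid)
                    )
                except ValueError as exc:
                    warnings.warn(str(exc))
        self.evaluator = ForceEvaluator(self.mesh, config.energy)
        self.events: List[dict] = []
        self.stats_rows: List[SummaryStats] = []
        self.first_lumen_time: Optional[float] = None
        self._step_index = 0
        self._tip_forces = np.zeros_like(self.mesh.positions)
        self._epi_vids = epithelial_only_vertices(self.mesh)
        self._epi_vids_version = self.mesh.topology_version
        self._field = None
        self._morphogen_params = self._effective_morphogen()
        self._solve_field()
        self._record_stats()

    # ------------------------------------------------------------------
    def _effective_morphogen(self) -> MorphogenParams:
        p = self.config.morphogen
        if self.config.vegfa_ko:
            return MorphogenParams(
                diffusivity=p.diffusivity,
                source_rate=0.0,
                degradation=p.degradation,
            )
        return p

    def _solve_field(self) -> None:
        if not self.config.chemotaxis_enabled:
            self._tip_forces = np.zeros_like(self.mesh.positions)
            return
        self._field = solve_vegf_field(self.mesh, self._morphogen_params)
        self._refresh_tip_forces()

    def _refresh_tip_forces(self) -> None:
        if self._field is None or not self.config.chemotaxis_enabled:
            self._tip_forces = np.zeros_like(self.mesh.positions)
            return
        self._tip_forces = tip_motile_forces(
            self.mesh, self._field, self.config.chemotaxis
        )

    def _refresh_epi_vids(self) -> None:
        if self._epi_vids_version != self.mesh.topology_version:
            self._epi_vids = epithelial_only_vertices(self.mesh)
            self._epi_vids_version = self.mesh.topology_version

    def _record_stats(self) -> None:
        self.stats_rows.append(
            compute_summary_stats(self.mesh, self.config.prolif)
        )

    # ------------------------------------------------------------------
    def step(self) -> None:
        """Advance the simulation by one time step ``dt``."""
        cfg = self.config
        mesh = self.mesh
        i = self._step_index

        if cfg.chemotaxis_enabled and i % cfg.field_cadence == 0 and i > 0:
            self._solve_field()
        if (
            cfg.polarity_enabled
            and i % cfg.polarity_cadence == 0
        ):
            update_polarity(
                mesh, cfg.polarity, cfg.polarity_cadence * cfg.dt
            )

        forces = self.evaluator.forces()
        if self._tip_forces.shape != forces.shape:
            self._refresh_tip_forces()
        forces = forces + self._tip_forces
        euler_step(mesh, forces, cfg.dt)

        if cfg.corridors_enabled and self.boundaries:
            self._refresh_epi_vids()
            enforce_corridors(mesh, self.boundaries, self._epi_vids)

        if i % cfg.event_cadence == 0:
            self._handle_events(cfg.event_cadence * cfg.dt)

        self._step_index += 1

    def _handle_events(self, dt_event: float) -> None:
        cfg = self.config
        mesh = self.mesh
        version0 = mesh.topology_version

        resolve_interpenetrations(mesh)
        rearrangement_sweep(mesh, cfg.thresholds)

        lumen_makers: set = set()
        if cfg.polarity_enabled:
            for cid in check_polarised_division(mesh, cfg.polarity):
                lid = create_lumen(mesh, cid, cfg.lumen)
                if lid is not None:
                    lumen_makers.add(cid)
                    self.events.append(
                        {
                            "time": mesh.time,
                            "cell": cid,
                            "event": "lumen_created",
                            "lumen": lid,
                        }
                    )
                    if self.first_lumen_time is None:
                        self.first_lumen_time = mesh.time
            grow_lumina(mesh, cfg.lumen, dt_event)

        if cfg.proliferation_enabled:
            self.events.extend(
                advance_cycles_and_divide(
                    mesh, cfg.prolif, dt_event, self.rng, skip=lumen_makers
                )
            )
            grow_target_areas(
                mesh, cfg.energy.A0_init, dt_event, cfg.prolif, cfg.endo
            )
            self.events.extend(stalk_divide_if_elongated(mesh, cfg.endo))

        if (
            cfg.branch_addition_enabled
            and mesh.time < cfg.endo.branch_addition_cutoff
            and self.rng.random() < cfg.endo.branch_addition_rate * dt_event
        ):
            added = add_endothelial_branch(mesh, cfg.endo, mesh.time, self.rng)
            if added is not None:
                tip_id, stalk_id = added
                self.events.append(
                    {
                        "time": mesh.time,
                        "event": "branch_added",
                        "tip": tip_id,
                        "stalk": stalk_id,
                    }
                )
                if cfg.corridors_enabled:
                    self.boundaries.append(
                        register_endo_boundary(
                            mesh, stalk_id, fix_vertices=False
                        )
                    )

        if mesh.topology_version != version0:
            rearrangement_sweep(mesh, cfg.thresholds)

        # a repair inside the sweep can tangle a cell scanned earlier in
        # the same pass; iterate repair+sweep until no ring crosses
        from .rearrange import repair_folds

        for _ in range(3):
            if repair_folds(mesh, cfg.thresholds) == 0:
                break
            rearrangement_sweep(mesh, cfg.thresholds)

        classify_peripherality(mesh)
        self.evaluator.ensure_fresh()
        self.evaluator.sync_states()
        self._refresh_tip_forces()

    def finalize(self) -> None:
        """Leave the mesh in a fully cleaned state (the last few
        integration steps of a run may fall between event intervals)."""
        from .rearrange import repair_folds

        cfg = self.config
        resolve_interpenetrations(self.mesh)
        rearrangement_sweep(self.mesh, cfg.thresholds)
        for _ in range(3):
            if repair_folds(self.mesh, cfg.thresholds) == 0:
                break
            rearrangement_sweep(self.mesh, cfg.thresholds)
        self.evaluator.ensure_fresh()
        self.evaluator.sync_states()

    # ------------------------------------------------------------------
    def run(self, out_dir=None) -> RunResult:
        cfg = self.config
        n_steps = int(round(cfg.duration / cfg.dt))
        stats_every = max(int(round(cfg.stats_interval / cfg.dt)), 1)
        snap_every = (
            max(int(round(cfg.snapshot_interval / cfg.dt)), 1)
            if cfg.snapshot_interval > 0
            else 0
        )
        out_path = Path(out_dir) if out_dir is not None else None
        if out_path is not None:
            out_path.mkdir(parents=True, exist_ok=True)

        for k in range(n_steps):
            self.step()
            if (k + 1) % stats_every == 0 or k == n_steps - 1:
                self._record_stats()
            if out_path is not None and snap_every and (k + 1) % snap_every == 0:
                self.write_snapshot(
                    out_path / f"snapshot_t{self.mesh.time:07.2f}.json"
                )
        if n_steps > 0:
            self.finalize()

        stats = pd.DataFrame([s.as_dict() for s in self.stats_rows])
        if out_path is not None:
            stats.to_csv(out_path / "stats.csv", index=False)
            with open(out_path / "events.log", "w") as fh:
                for ev in self.events:
                    fh.write(json.dumps(ev) + "\n")
            if self.events:
                pd.DataFrame(self.events).to_csv(
                    out_path / "events.csv", index=False
                )
        return RunResult(
            mesh=self.mesh,
            stats=stats,
            events=self.events,
            boundaries=self.boundaries,
            first_lumen_time=self.first_lumen_time,
            config=cfg,
        )

    def write_snapshot(self, path) -> None:
        from .snapshots import write_snapshot_json

        write_snapshot_json(
            path, self.mesh, boundaries=self.boundaries, field=self._field
        )


def run(config: RunConfig, ic: Optional[InitialCondition] = None, out_dir=None) -> RunResult:
    """Run a full simulation described by ``config``."""
    return Simulation(config, ic=ic).run(out_dir=out_dir)
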