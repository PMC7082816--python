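"""Case assembly: tie a geometry, score map and pressure set to one reusable
forward model with caching and warm starting across parameter sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry as geo
from .materials import (
    ActiveLaw,
    GlobalParameters,
    PassiveLaw,
    ScoreMap17,
    SectorParameters,
)
from .mechanics import FEModel, PressureSet, SimulationState, StrainTable, sector_strains

__all__ = ["Case", "CaseRunner", "build_mesh"]


@dataclass
class Case:
    """Complete problem definition short of the unknown global parameters."""

    geometry: geo.IdealizedGeometry = field(default_factory=geo.IdealizedGeometry)
    density: geo.MeshDensity = field(default_factory=geo.MeshDensity)
    pressures: PressureSet = field(default_factory=lambda: PressureSet(10, 120, 8, 25))
    scores: ScoreMap17 = field(default_factory=ScoreMap17.zeros)
    active: ActiveLaw = field(default_factory=ActiveLaw)
    kappa: float = 1.0e3
    W_vol: float = 10.0
    n_steps: int = 10
    tol: float = 1.0e-8

    def runner(self) -> "CaseRunner":
        return CaseRunner(self)

    def with_density(self, density: geo.MeshDensity) -> "Case":
        return replace(self, density=density)


def build_mesh(geometry: geo.IdealizedGeometry, density: geo.MeshDensity) -> geo.HexMesh:
    """Mesh, septum (ray cast against the synthetic RV shell), AHA partition
    and fiber assignment in one call."""
    mesh = geo.generate_idealized_lv(geometry, density)
    rv = geo.make_rv_endo_shell(geometry)
    septal = geo.detect_septum(mesh, rv)
    geo.partition_aha17(mesh, septal)
    geo.assign_fibers(mesh)
    return mesh


class CaseRunner:
    """Forward solves for one case with (C_H, Tmax_H, alpha) as free inputs.

    ED states are cached per C_H and ES states per (C_H, Tmax_H, alpha); both
    solves warm-start from the most recent converged state of their phase,
    which makes optimizer sweeps cheap.  All solves are deterministic.
    """

    def __init__(self, case: Case):
        self.case = case
        self.mesh = build_mesh(case.geometry, case.density)
        self.scores = case.scores
        self.pressures = case.pressures
        # the model is built once; per-trial parameters are swapped in place
        params0 = SectorParameters.from_scores(
            GlobalParameters(1.0, 0.0, 0.0, case.W_vol), case.scores
        )
        self.model = FEModel(
            self.mesh,
            params0,
            PassiveLaw(C=1.0, kappa=case.kappa),
            case.active,
            case.pressures,
            n_steps=case.n_steps,
            tol=case.tol,
        )
        self.reference_volume = self.model.reference_volume
        self._ed_cache: dict = {}
        self._es_cache: dict = {}
        self._last_ed: np.ndarray | None = None
        self._last_es: np.ndarray | None = None
        self.n_ed_solves = 0
        self.n_es_solves = 0

    # -----------------------------------------------------------------
    def set_parameters(self, C_H: float, Tmax_H: float, alpha: float) -> None:
        """Pin the model's sector parameters (needed before residual-based
        diagnostics on a cached state, since solves for other parameter sets
        overwrite the shared assembly in place)."""
        self._set_params(C_H, Tmax_H, alpha)

    def _set_params(self, C_H: float, Tmax_H: float, alpha: float) -> None:
        params = SectorParameters.from_scores(
            GlobalParameters(C_H, Tmax_H, alpha, self.case.W_vol), self.scores
        )
        sec = self.mesh.element_sector - 1
        self.model.C_elem = np.asarray(params.C_n)[sec]
        self.model.Tmax_elem = np.asarray(params.Tmax_n)[sec]
        self.model.assembly.C_elem = self.model.C_elem
        self.model.assembly.Tmax_elem = self.model.Tmax_elem

    @staticmethod
    def _key(*vals) -> tuple:
        return tuple(round(float(v), 12) for v in vals)

    def ed_state(self, C_H: float) -> SimulationState:
        key = self._key(C_H)
        if key not in self._ed_cache:
            self._set_params(C_H, 0.0, 0.0)
            state = self.model.solve_ed(warm_start=self._last_ed)
            self._ed_cache[key] = state
            self._last_ed = state.displacement
            self.n_ed_solves += 1
        return self._ed_cache[key]

    def es_state(self, C_H: float, Tmax_H: float, alpha: float) -> SimulationState:
        key = self._key(C_H, Tmax_H, alpha)
        if key not in self._es_cache:
            ed = self.ed_state(C_H)
            self._set_params(C_H, Tmax_H, alpha)
            state = self.model.solve_es(ed, warm_start=self._last_es)
            self._es_cache[key] = state
            self._last_es = state.displacement
            self.n_es_solves += 1
        return self._es_cache[key]

    def strain_table(self, C_H: float, Tmax_H: float, alpha: float) -> StrainTable:
        ed = self.ed_state(C_H)
        es = self.es_state(C_H, Tmax_H, alpha)
        return sector_strains(ed, es, self.mesh)

    def edv(self, C_H: float) -> float:
        return self.ed_state(C_H).volume_ml

    def clear_cache(self) -> None:
        self._ed_cache.clear()
        self._es_cache.clear()
        self._last_ed = None
        self._last_es = None
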