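"""Quasi-static LV mechanics: passive inflation to end-diastole, active
contraction to end-systole, and sector-averaged Green-Lagrange strains.

The solver is an implicit Newton scheme with incremental load stepping (the
two equilibria of interest are end-diastole and end-systole; the path between
them is continuation only).  The meshed geometry is taken as the stress-free
reference; reported strains use the end-diastolic state as reference, matching
tagged-CMR strain measured from tags laid at end-diastole.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fem
from .geometry import HexMesh, cavity_volume
from .materials import ActiveLaw, PassiveLaw, SectorParameters

MMHG_TO_KPA = 0.133322

__all__ = [
    "MMHG_TO_KPA",
    "PressureSet",
    "SimulationState",
    "StrainTable",
    "FEModel",
    "solve_passive_inflation",
    "solve_end_systole",
    "sector_strains",
]


@dataclass(frozen=True)
class PressureSet:
    """LV/RV end-diastolic and end-systolic pressures in mmHg."""

    lv_edp: float
    lv_esp: float
    rv_edp: float
    rv_esp: float
    ef: float | None = None  # measured ejection fraction (%), bookkeeping only

    def __post_init__(self) -> None:
        if min(self.lv_edp, self.lv_esp, self.rv_edp, self.rv_esp) < 0:
            raise ValueError("pressures must be non-negative")
        if self.lv_esp <= self.lv_edp or self.rv_esp <= self.rv_edp:
            raise ValueError("end-systolic pressure must exceed end-diastolic")

    def kpa(self, name: str) -> float:
        return getattr(self, name) * MMHG_TO_KPA


@dataclass
class SimulationState:
    """Converged equilibrium: displacements (mm), volume (ml), diagnostics."""

    displacement: np.ndarray
    volume_ml: float
    phase: str
    residual_norm: float
    load_steps: int
    newton_iterations: int


class StrainTable:
    """Per-sector end-systolic strains (E_cc, E_ll, E_rr) plus EDV/ESV.

    Sector 17 (the apex cap) is flagged ``excluded`` and never enters the
    optimization objective.
    """

    def __init__(self, e_cc, e_ll, e_rr, edv: float, esv: float):
        e_cc, e_ll, e_rr = (np.asarray(v, dtype=float) for v in (e_cc, e_ll, e_rr))
        if e_cc.shape != (17,) or e_ll.shape != (17,) or e_rr.shape != (17,):
            raise ValueError("strain tables have exactly 17 sectors")
        if not (np.isfinite(e_cc).all() and np.isfinite(e_ll).all()
                and np.isfinite(e_rr).all()):
            raise ValueError("strains must be finite")
        self.df = pd.DataFrame(
            {
                "sector": np.arange(1, 18),
                "E_cc": e_cc,
                "E_ll": e_ll,
                "E_rr": e_rr,
                "excluded": np.arange(1, 18) == 17,
            }
        )
        self.edv = float(edv)
        self.esv = float(esv)

    @property
    def e_cc(self) -> np.ndarray:
        return self.df["E_cc"].to_numpy()

    @property
    def e_ll(self) -> np.ndarray:
        return self.df["E_ll"].to_numpy()

    @property
    def e_rr(self) -> np.ndarray:
        return self.df["E_rr"].to_numpy()

    def included(self) -> pd.DataFrame:
        return self.df[~self.df["excluded"]]

    def to_csv(self, path) -> None:
        df = self.df.copy()
        df["EDV_ml"] = self.edv
        df["ESV_ml"] = self.esv
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StrainTable":
        df = pd.read_csv(path).sort_values("sector")
        return cls(
            df["E_cc"].to_numpy(), df["E_ll"].to_numpy(), df["E_rr"].to_numpy(),
            float(df["EDV_ml"].iloc[0]), float(df["ESV_ml"].iloc[0]),
        )

    def volumes_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"EDV_ml": self.edv, "ESV_ml": self.esv}, fh, indent=1)


class FEModel:
    """Forward mechanics model for one labeled, fibered mesh.

    Builds the finite-element assembly for a given set of sector parameters
    and exposes the two equilibrium solves.  ES solves can be warm-started
    from a previous ES displacement, which accelerates optimization sweeps.
    """

    def __init__(
        self,
        mesh: HexMesh,
        sector_params: SectorParameters,
        passive: PassiveLaw,
        active: ActiveLaw,
        pressures: PressureSet,
        n_steps: int = 10,
        tol: float = 1.0e-8,
    ):
        if mesh.fiber_vector is None:
            raise RuntimeError("mesh has no fiber field; call assign_fibers first")
        if (mesh.element_sector < 1).any():
            raise RuntimeError("mesh has unlabeled elements; run partition_aha17")
        self.mesh = mesh
        self.pressures = pressures
        self.n_steps = n_steps
        self.tol = tol
        sec = mesh.element_sector - 1
        self.C_elem = np.asarray(sector_params.C_n)[sec]
        self.Tmax_elem = np.asarray(sector_params.Tmax_n)[sec]
        self.assembly = _fem.Assembly(
            mesh, self.C_elem, self.Tmax_elem, passive, active
        )
        self.reference_volume = cavity_volume(mesh)

    def solve_ed(self, warm_start: np.ndarray | None = None) -> SimulationState:
        """Passive inflation to (LV_EDP, RV_EDP); no activation.

        ``warm_start`` may hold the ED displacement of a nearby stiffness;
        a direct Newton solve is attempted from it before falling back to the
        usual zero-state ramp.
        """
        p_lv = self.pressures.kpa("lv_edp")
        p_rv = self.pressures.kpa("rv_edp")
        if warm_start is not None:
            try:
                u, info = self.assembly.solve(
                    warm_start, p_lv, p_rv, 0.0,
                    start=(p_lv, p_rv, 0.0), n_steps=1, tol=self.tol,
                    try_direct=True, max_bisect=0,
                )
                vol = cavity_volume(self.mesh, u.reshape(-1, 3))
                return SimulationState(u, vol, "ED", info.residual_norm,
                                       info.load_steps, info.newton_iterations)
            except (_fem.NonConvergenceError, ValueError):
                pass
        try:
            u, info = self.assembly.solve(
                None, p_lv, p_rv, 0.0, n_steps=self.n_steps, tol=self.tol
            )
        except _fem.NonConvergenceError:
            # very soft wall: continue in the stiffness scale instead
            u, info = self.assembly.solve_stiff_homotopy(
                p_lv, p_rv, n_steps=self.n_steps, tol=self.tol
            )
        vol = cavity_volume(self.mesh, u.reshape(-1, 3))
        return SimulationState(u, vol, "ED", info.residual_norm,
                               info.load_steps, info.newton_iterations)

    def solve_es(
        self, ed: SimulationState, warm_start: np.ndarray | None = None
    ) -> SimulationState:
        """Active contraction to (LV_ESP, RV_ESP) with full activation,
        continued jointly in pressure and activation from the ED state."""
        p_lv_ed = self.pressures.kpa("lv_edp")
        p_rv_ed = self.pressures.kpa("rv_edp")
        p_lv = self.pressures.kpa("lv_esp")
        p_rv = self.pressures.kpa("rv_esp")
        if warm_start is not None:
            try:
                u, info = self.assembly.solve(
                    warm_start, p_lv, p_rv, 1.0,
                    start=(p_lv, p_rv, 1.0), n_steps=1, tol=self.tol,
                    try_direct=True, max_bisect=0,
                )
                vol = cavity_volume(self.mesh, u.reshape(-1, 3))
                return SimulationState(u, vol, "ES", info.residual_norm,
                                       info.load_steps, info.newton_iterations)
            except (_fem.NonConvergenceError, ValueError):
                pass
        u, info = self.assembly.solve(
            ed.displacement, p_lv, p_rv, 1.0,
            start=(p_lv_ed, p_rv_ed, 0.0), n_steps=self.n_steps, tol=self.tol,
        )
        vol = cavity_volume(self.mesh, u.reshape(-1, 3))
        return SimulationState(u, vol, "ES", info.residual_norm,
                               info.load_steps, info.newton_iterations)

    # -- diagnostics ----------------------------------------------------
    def element_jacobians(self, state: SimulationState) -> np.ndarray:
        """Element-average deformation Jacobian det(F) at a converged state."""
        ue = state.displacement.reshape(-1, 3)[self.mesh.elements]
        F = np.eye(3) + np.einsum("eai,egaJ->egiJ", ue, self.assembly.dNdX)
        return np.linalg.det(F).mean(axis=1)

    def basal_reaction_z(self, state: SimulationState) -> float:
        """Net z reaction on the constrained basal nodes (mN)."""
        a = self.assembly
        p_lv = self.pressures.kpa("lv_edp" if state.phase == "ED" else "lv_esp")
        p_rv = self.pressures.kpa("rv_edp" if state.phase == "ED" else "rv_esp")
        act = 0.0 if state.phase == "ED" else 1.0
        r, _, _ = a.residual_tangent(state.displacement, p_lv, p_rv, act)
        fixed_z = 3 * a.base_nodes + 2
        return float(r[fixed_z].sum())

    def external_force_z(self, state: SimulationState) -> float:
        """Net z component of the applied pressure loads (mN)."""
        a = self.assembly
        p_lv = self.pressures.kpa("lv_edp" if state.phase == "ED" else "lv_esp")
        p_rv = self.pressures.kpa("rv_edp" if state.phase == "ED" else "rv_esp")
        x = self.mesh.nodes + state.displacement.reshape(-1, 3)
        fz = 0.0
        for name, p in (("endo", p_lv), ("septal_epi", p_rv)):
            if p != 0.0 and name in a.facets:
                fv, _ = a._pressure_terms(x, name, p)
                fz += fv.reshape(-1, 3)[:, 2].sum()
        return float(fz)


def solve_passive_inflation(
    mesh: HexMesh,
    sector_params: SectorParameters,
    pressures: PressureSet,
    passive: PassiveLaw | None = None,
    active: ActiveLaw | None = None,
    **kw,
) -> SimulationState:
    model = FEModel(mesh, sector_params, passive or PassiveLaw(),
                    active or ActiveLaw(), pressures, **kw)
    return model.solve_ed()


def solve_end_systole(
    mesh: HexMesh,
    sector_params: SectorParameters,
    pressures: PressureSet,
    ed_state: SimulationState | None = None,
    passive: PassiveLaw | None = None,
    active: ActiveLaw | None = None,
    **kw,
) -> SimulationState:
    model = FEModel(mesh, sector_params, passive or PassiveLaw(),
                    active or ActiveLaw(), pressures, **kw)
    if ed_state is None:
        ed_state = model.solve_ed()
    return model.solve_es(ed_state)


def sector_strains(
    ed: SimulationState, es: SimulationState, mesh: HexMesh
) -> StrainTable:
    """Volume-weighted sector averages of the ED->ES Green-Lagrange strain.

    The relative deformation gradient F_rel = F_ES F_ED^-1 is formed per
    element (at the centroid), its Green-Lagrange tensor rotated into the
    local (e_c, e_l, e_r) frame, and averaged per sector with reference
    element volumes as weights.
    """
    if ed is None or es is None:
        raise RuntimeError("both ED and ES states are required")
    dN0 = _fem._shape_grad_at(np.zeros(3))[0]
    Xe = mesh.nodes[mesh.elements]
    J0 = np.einsum("eai,aj->eij", Xe, dN0)
    Jinv = np.linalg.inv(J0)
    dNdX = np.einsum("aj,eji->eai", dN0, Jinv)
    eye = np.eye(3)

    def grad(u):
        return eye + np.einsum("eai,eaJ->eiJ", u.reshape(-1, 3)[mesh.elements], dNdX)

    F_ed = grad(ed.displacement)
    F_es = grad(es.displacement)
    F_rel = np.einsum("eiJ,eJK->eiK", F_es, np.linalg.inv(F_ed))
    E = 0.5 * (np.einsum("eiI,eiJ->eIJ", F_rel, F_rel) - eye)

    frames = np.stack(
        [mesh.element_frame_c, mesh.element_frame_l, mesh.element_frame_r], axis=-1
    )
    El = np.einsum("eba,ebc,ecd->ead", frames, E, frames)
    vol = np.abs(np.linalg.det(J0)) * 8.0

    e_cc = np.zeros(17)
    e_ll = np.zeros(17)
    e_rr = np.zeros(17)
    for s in range(1, 18):
        m = mesh.element_sector == s
        if not m.any():
            continue
        w = vol[m] / vol[m].sum()
        e_cc[s - 1] = np.sum(w * El[m, 0, 0])
        e_ll[s - 1] = np.sum(w * El[m, 1, 1])
        e_rr[s - 1] = np.sum(w * El[m, 2, 2])
    return StrainTable(e_cc, e_ll, e_rr, ed.volume_ml, es.volume_ml)
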