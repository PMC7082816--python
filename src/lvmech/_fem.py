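"""Vectorized total-Lagrangian finite-element core for hex8 meshes.

One assembly object is built per (mesh, sector parameters) combination; it
exposes residual/tangent evaluation and a Newton solver with incremental load
stepping.  Design notes:

* full 2x2x2 Gauss integration of the anisotropic (Guccione + active) stress,
  selective reduced integration (element centroid) of the volumetric penalty
  to avoid near-incompressible locking;
* follower pressure loads on the endocardial and septal-epicardial facet
  sets, including their (unsymmetric) load-stiffness contribution;
* basal nodes fixed in z; the whole-body mean lateral displacement and the
  basal-ring twist are removed by a weak quadratic penalty, giving the
  one-sided RV septal load a static reaction path and suppressing the
  mesh-sensitive pendulum mode about the sliding base (torsion unaffected).

Units: mm, kPa (= mN/mm^2), so forces are mN and volumes mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import ActiveLaw, PassiveLaw, active_tension_and_slope

_EPS3 = np.zeros((3, 3, 3))
for _i, _j, _k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
    _EPS3[_i, _j, _k] = 1.0
    _EPS3[_i, _k, _j] = -1.0

_LOCAL_COORDS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)

_G = 1.0 / np.sqrt(3.0)
_GAUSS = np.array(
    [[sx * _G, sy * _G, sz * _G] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)


def _shape_grad_at(xi: np.ndarray) -> np.ndarray:
    """(n_pts, 8, 3) gradients of trilinear shape functions at local coords."""
    xi = np.atleast_2d(xi)
    g = np.empty((len(xi), 8, 3))
    for a in range(8):
        sa = _LOCAL_COORDS[a]
        g[:, a, 0] = 0.125 * sa[0] * (1 + sa[1] * xi[:, 1]) * (1 + sa[2] * xi[:, 2])
        g[:, a, 1] = 0.125 * sa[1] * (1 + sa[0] * xi[:, 0]) * (1 + sa[2] * xi[:, 2])
        g[:, a, 2] = 0.125 * sa[2] * (1 + sa[0] * xi[:, 0]) * (1 + sa[1] * xi[:, 1])
    return g


def shape_gradients() -> np.ndarray:
    """Gradients at the 8 Gauss points, shape (8, 8, 3)."""
    return _shape_grad_at(_GAUSS)


class NonConvergenceError(RuntimeError):
    """Newton iteration failed even after load-step bisection."""


class _DivergedState(RuntimeError):
    """Trial iterate left the admissible deformation range (det F <= 0)."""


@dataclass
class SolveInfo:
    load_steps: int = 0
    newton_iterations: int = 0
    residual_norm: float = np.nan
    bisections: int = 0


class Assembly:
    """Residual/tangent assembly for one mesh + material parameter set."""

    def __init__(
        self,
        mesh,
        C_elem: np.ndarray,
        Tmax_elem: np.ndarray,
        passive: PassiveLaw,
        active: ActiveLaw,
        base_penalty: float = 1.0e5,
    ):
        self.mesh = mesh
        self.passive = passive
        self.active = active
        self.C_elem = np.asarray(C_elem, dtype=float)
        self.Tmax_elem = np.asarray(Tmax_elem, dtype=float)

        X = mesh.nodes
        conn = mesh.elements
        self.conn = conn
        self.n_dof = 3 * len(X)

        # --- volume integration data ------------------------------------
        dN_loc = shape_gradients()                       # (G,8,3)
        Jmap = np.einsum("eai,gaj->egij", X[conn], dN_loc)
        detJ = np.linalg.det(Jmap)
        if detJ.min() <= 0:
            raise ValueError("mesh has non-positive Jacobians")
        Jinv = np.linalg.inv(Jmap)
        self.dNdX = np.einsum("gaj,egji->egai", dN_loc, Jinv)   # (E,G,8,3)
        self.w = detJ                                            # unit weights

        dN0 = _shape_grad_at(np.zeros(3))                # centroid
        J0 = np.einsum("eai,gaj->egij", X[conn], dN0)
        det0 = np.linalg.det(J0)
        self.dNdX0 = np.einsum("gaj,egji->egai", dN0, np.linalg.inv(J0))
        self.Ve = 8.0 * det0[:, 0]                       # element ref volume

        # --- per-Gauss-point fiber frames -------------------------------
        from .geometry import fiber_at

        t_gp = (mesh.element_layer[:, None] + 0.5 * (_GAUSS[:, 2][None, :] + 1.0)) \
            / mesh.n_transmural
        eids = np.repeat(np.arange(len(conn))[:, None], len(_GAUSS), axis=1)
        f = fiber_at(mesh, t_gp, eids)                   # (E,G,3)
        er = mesh.element_frame_r[:, None, :] * np.ones_like(f)
        s = np.cross(er, f)
        s /= np.linalg.norm(s, axis=-1, keepdims=True)
        self.R = np.stack([f, s, er], axis=-1)           # columns f, s, r

        bf, bt, bfs = passive.b_f, passive.b_t, passive.b_fs
        self.Bmat = np.array([[bf, bfs, bfs], [bfs, bt, bt], [bfs, bt, bt]])
        eye = np.eye(3)
        self.B4 = 0.5 * self.Bmat[:, :, None, None] * (
            np.einsum("ik,jl->ijkl", eye, eye) + np.einsum("il,jk->ijkl", eye, eye)
        )

        # --- scatter indices --------------------------------------------
        dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(len(conn), 24)
        self.rows_e = np.repeat(dof, 24, axis=1).ravel()
        self.cols_e = np.tile(dof, (1, 24)).ravel()
        self.dof_e = dof

        # --- pressure facets --------------------------------------------
        self.facets = {}
        for name in ("endo", "septal_epi"):
            if name in mesh.facet_sets:
                self._init_facets(name, mesh.facet_sets[name])

        # --- boundary conditions ----------------------------------------
        base_nodes = np.unique(mesh.facet_sets["base"])
        base_nodes = base_nodes[np.isclose(X[base_nodes, 2], 0.0)]
        self.base_nodes = base_nodes
        fixed = 3 * base_nodes + 2                       # u_z = 0 on the base
        self.free = np.setdiff1d(np.arange(self.n_dof), fixed)

        # low-energy mode control: the one-sided septal load would otherwise
        # tip the ventricle about its sliding base (a pendulum mode whose only
        # stiffness is mesh-dependent wall bending), so the *whole-body* mean
        # lateral displacement is penalized; the basal-ring twist penalty
        # removes the remaining in-plane rigid mode without touching torsion
        nb = len(base_nodes)
        nn = len(X)
        r_xy = X[base_nodes, :2]
        rad = np.linalg.norm(r_xy, axis=1).mean()
        g = np.zeros((3, self.n_dof))
        g[0, 0::3] = 1.0 / nn                    # mean u_x, all nodes
        g[1, 1::3] = 1.0 / nn                    # mean u_y, all nodes
        g[2, 3 * base_nodes + 0] = -r_xy[:, 1] / (nb * rad)
        g[2, 3 * base_nodes + 1] = r_xy[:, 0] / (nb * rad)
        self.rigid_modes = g
        self.base_penalty = base_penalty
        gs = sp.csr_matrix(g)
        self._K_pen = (base_penalty * (gs.T @ gs)).tocsr()

    # ------------------------------------------------------------------
    def _init_facets(self, name: str, quads: np.ndarray) -> None:
        gl = 1.0 / np.sqrt(3.0)
        gp = np.array([[-gl, -gl], [gl, -gl], [gl, gl], [-gl, gl]])
        loc = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
        N = 0.25 * (1 + loc[None, :, 0] * gp[:, 0, None]) * (
            1 + loc[None, :, 1] * gp[:, 1, None]
        )                                                   # (G4,4)
        dN = np.empty((4, 4, 2))
        dN[:, :, 0] = 0.25 * loc[None, :, 0] * (1 + loc[None, :, 1] * gp[:, 1, None])
        dN[:, :, 1] = 0.25 * loc[None, :, 1] * (1 + loc[None, :, 0] * gp[:, 0, None])
        dofq = (3 * quads[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        self.facets[name] = {
            "quads": quads,
            "N": N,
            "dN": dN,
            "dof": dofq,
            "rows": np.repeat(dofq, 12, axis=1).ravel(),
            "cols": np.tile(dofq, (1, 12)).ravel(),
        }

    # ------------------------------------------------------------------
    def _pressure_terms(self, x: np.ndarray, name: str, p: float):
        """Follower-load nodal forces and load-stiffness triplets."""
        fa = self.facets[name]
        quads, N, dN = fa["quads"], fa["N"], fa["dN"]
        xq = x[quads]                                       # (K,4,3)
        g1 = np.einsum("gb,kbi->kgi", dN[:, :, 0], xq)
        g2 = np.einsum("gb,kbi->kgi", dN[:, :, 1], xq)
        tvec = np.cross(g1, g2)                             # n da per unit dxi
        f = -p * np.einsum("ga,kgi->kai", N, tvec)          # (K,4,3)
        # dt_i/dx_bj = eps_ijc (g2_c dN1_b - g1_c dN2_b)
        dt = np.einsum("ijc,kgc,gb->kgibj", _EPS3, g2, dN[:, :, 0]) \
            - np.einsum("ijc,kgc,gb->kgibj", _EPS3, g1, dN[:, :, 1])
        K = -p * np.einsum("ga,kgibj->kaibj", N, dt)        # (K,4,3,4,3)
        fvec = np.zeros(self.n_dof)
        np.add.at(fvec, fa["dof"].ravel(), f.reshape(len(quads), -1).ravel())
        return fvec, K.reshape(len(quads), -1)

    # ------------------------------------------------------------------
    def residual_tangent(
        self, u: np.ndarray, p_lv: float, p_rv: float, activation: float,
        want_tangent: bool = True,
    ):
        """Assembled residual (internal - external) and tangent matrix.

        With ``want_tangent=False`` only the residual is formed (used by the
        line search), and the tangent slot of the return value is None.
        """
        conn = self.conn
        ue = u.reshape(-1, 3)[conn]                         # (E,8,3)
        eyeF = np.eye(3)

        # deviatoric/anisotropic part at the 8 Gauss points
        F = eyeF + np.einsum("eai,egaJ->egiJ", ue, self.dNdX, optimize=True)
        E = 0.5 * (np.einsum("egiI,egiJ->egIJ", F, F, optimize=True) - eyeF)
        R = self.R
        El = np.einsum("egba,egbc,egcd->egad", R, E, R, optimize=True)
        Q = np.einsum("ij,egij->eg", self.Bmat, El * El)
        CeQ = self.C_elem[:, None] * np.exp(np.minimum(Q, 60.0))
        BE = self.Bmat * El
        Sl = CeQ[..., None, None] * BE
        if want_tangent:
            Dl = CeQ[..., None, None, None, None] * self.B4 \
                + 2.0 * CeQ[..., None, None, None, None] * np.einsum(
                    "egij,egkl->egijkl", BE, BE
                )
        if activation > 0.0:
            T0, dT0 = active_tension_and_slope(
                El[..., 0, 0], self.Tmax_elem[:, None], self.active
            )
            Sl[..., 0, 0] += activation * T0
            cf = self.active.crossfiber_fraction
            if cf > 0.0:
                Sl[..., 1, 1] += cf * activation * T0
            if want_tangent:
                Dl[..., 0, 0, 0, 0] += activation * dT0
                if cf > 0.0:
                    Dl[..., 1, 1, 0, 0] += cf * activation * dT0
        S = np.einsum("egab,egbc,egdc->egad", R, Sl, R, optimize=True)
        if want_tangent:
            D = np.einsum("egai,egijkl->egajkl", R, Dl, optimize=True)
            D = np.einsum("egbj,egajkl->egabkl", R, D, optimize=True)
            D = np.einsum("egck,egabkl->egabcl", R, D, optimize=True)
            D = np.einsum("egdl,egabcl->egabcd", R, D, optimize=True)

        # volumetric penalty at the centroid
        F0 = eyeF + np.einsum("eai,egaJ->egiJ", ue, self.dNdX0)
        detF0 = np.linalg.det(F0)
        if detF0.min() <= 1e-8:
            raise _DivergedState("element inversion in trial state")
        C0 = np.einsum("egiI,egiJ->egIJ", F0, F0)
        J0 = detF0
        Ci = np.linalg.inv(C0)
        kap = self.passive.kappa
        S0 = kap * ((J0 - 1.0) * J0)[..., None, None] * Ci
        if want_tangent:
            D0 = kap * ((2.0 * J0 - 1.0) * J0)[..., None, None, None, None] * np.einsum(
                "egij,egkl->egijkl", Ci, Ci
            ) - kap * ((J0 - 1.0) * J0)[..., None, None, None, None] * (
                np.einsum("egik,egjl->egijkl", Ci, Ci)
                + np.einsum("egil,egjk->egijkl", Ci, Ci)
            )

        # internal force
        P = np.einsum("egiI,egIJ->egiJ", F, S, optimize=True)
        fint_e = np.einsum("egaJ,egiJ,eg->eai", self.dNdX, P, self.w, optimize=True)
        P0 = np.einsum("egiI,egIJ->egiJ", F0, S0)
        fint_e += np.einsum("egaJ,egiJ,eg->eai", self.dNdX0, P0,
                            self.Ve[:, None] * np.ones_like(J0))
        fint = np.zeros(self.n_dof)
        np.add.at(fint, self.dof_e.ravel(), fint_e.reshape(-1))

        # tangent: material + geometric, gauss + centroid
        if want_tangent:
            A = np.einsum("egiI,egIJKL,egkK->egiJkL", F, D, F, optimize=True)
            Ke = np.einsum("egaJ,egiJkL,egbL,eg->eaibk", self.dNdX, A, self.dNdX,
                           self.w, optimize=True)
            G = np.einsum("egaJ,egJL,egbL,eg->eab", self.dNdX, S, self.dNdX,
                          self.w, optimize=True)
            Ke += np.einsum("eab,ik->eaibk", G, eyeF)
            A0 = np.einsum("egiI,egIJKL,egkK->egiJkL", F0, D0, F0, optimize=True)
            w0 = self.Ve[:, None] * np.ones_like(J0)
            Ke += np.einsum("egaJ,egiJkL,egbL,eg->eaibk", self.dNdX0, A0,
                            self.dNdX0, w0, optimize=True)
            G0 = np.einsum("egaJ,egJL,egbL,eg->eab", self.dNdX0, S0, self.dNdX0,
                           w0, optimize=True)
            Ke += np.einsum("eab,ik->eaibk", G0, eyeF)
            data = [Ke.reshape(-1)]
            rows = [self.rows_e]
            cols = [self.cols_e]

        # external follower pressures
        x = self.mesh.nodes + u.reshape(-1, 3)
        fext = np.zeros(self.n_dof)
        for name, p in (("endo", p_lv), ("septal_epi", p_rv)):
            if p != 0.0 and name in self.facets:
                fv, Kl = self._pressure_terms(x, name, p)
                fext += fv
                if want_tangent:
                    data.append(-Kl.ravel())                # K = dfint - dfext
                    rows.append(self.facets[name]["rows"])
                    cols.append(self.facets[name]["cols"])

        # basal rigid-mode penalty (enters as internal stiffness)
        fint += self.base_penalty * (self.rigid_modes.T @ (self.rigid_modes @ u))

        if not want_tangent:
            return fint - fext, None, np.linalg.norm(fext)
        K = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof),
        ).tocsr() + self._K_pen
        return fint - fext, K, np.linalg.norm(fext)

    # ------------------------------------------------------------------
    def newton(
        self,
        u: np.ndarray,
        p_lv: float,
        p_rv: float,
        activation: float,
        tol: float,
        max_iter: int,
        fref: float,
    ):
        """Damped Newton at fixed load; returns (u, iterations) or None.

        Each step is backtracked (up to 8 halvings) until the residual norm
        decreases and the trial state stays free of element inversion; this
        tames the overshoot the exponential material otherwise provokes.
        """
        u = u.copy()
        rn = np.inf
        for it in range(max_iter):
            try:
                r, K, fnorm = self.residual_tangent(u, p_lv, p_rv, activation)
            except _DivergedState:
                return None, it, rn
            scale = max(fref, fnorm, 1.0)
            rn = np.linalg.norm(r[self.free]) / scale
            if not np.isfinite(rn):
                return None, it, rn
            if rn < tol:
                return u, it, rn
            Kff = K[self.free][:, self.free]
            try:
                du = spla.spsolve(Kff.tocsc(), -r[self.free])
            except RuntimeError:
                return None, it, rn
            if not np.all(np.isfinite(du)):
                return None, it, rn
            alpha, accepted = 1.0, False
            for _ in range(8):
                u_try = u.copy()
                u_try[self.free] += alpha * du
                try:
                    r2, _, fn2 = self.residual_tangent(
                        u_try, p_lv, p_rv, activation, want_tangent=False
                    )
                except _DivergedState:
                    alpha *= 0.5
                    continue
                rn2 = np.linalg.norm(r2[self.free]) / max(fref, fn2, 1.0)
                if np.isfinite(rn2) and (rn2 < rn or rn2 < tol):
                    u, accepted = u_try, True
                    break
                alpha *= 0.5
            if not accepted:
                return None, it + 1, rn
        return None, max_iter, rn

    # ------------------------------------------------------------------
    def solve(
        self,
        u0: np.ndarray | None,
        p_lv: float,
        p_rv: float,
        activation: float,
        start=(0.0, 0.0, 0.0),
        n_steps: int = 10,
        tol: float = 1.0e-8,
        max_iter: int = 15,
        max_bisect: int = 8,
        try_direct: bool = False,
    ):
        """Ramp loads from ``start`` to the targets with Newton per step.

        Steps are halved (up to ``max_bisect`` times) on divergence.  With
        ``try_direct`` a single Newton solve at the target load is attempted
        first, which pays off when ``u0`` is a converged nearby state.
        """
        u = np.zeros(self.n_dof) if u0 is None else u0.copy()
        info = SolveInfo()
        p0_lv, p0_rv, a0 = start
        # reference force scale for relative convergence at the full load
        fref = self._external_norm(p_lv, p_rv, u)

        if try_direct:
            res, its, rn = self.newton(u, p_lv, p_rv, activation, tol, 12, fref)
            if res is not None:
                info.load_steps, info.newton_iterations, info.residual_norm = 1, its, rn
                return res, info
            info.bisections += 1                            # direct attempt failed

        lam, step = 0.0, 1.0 / n_steps
        step0 = step
        bis = 0
        while lam < 1.0 - 1e-12:
            lam_try = min(1.0, lam + step)
            pl = p0_lv + (p_lv - p0_lv) * lam_try
            pr = p0_rv + (p_rv - p0_rv) * lam_try
            ac = a0 + (activation - a0) * lam_try
            res, its, rn = self.newton(u, pl, pr, ac, tol, max_iter, fref)
            info.newton_iterations += its
            if res is None:
                bis += 1
                info.bisections += 1
                step *= 0.5
                if bis > max_bisect:
                    raise NonConvergenceError(
                        f"Newton diverged at load fraction {lam_try:.3f} "
                        f"(residual {rn:.2e}) after {max_bisect} bisections"
                    )
                continue
            u = res
            lam = lam_try
            info.load_steps += 1
            info.residual_norm = rn
            if its <= 6:           # easy step: grow back toward the base size
                step = min(2.0 * step, step0)
        return u, info

    def solve_stiff_homotopy(
        self,
        p_lv: float,
        p_rv: float,
        n_steps: int = 10,
        tol: float = 1.0e-8,
    ):
        """Passive solve via continuation in the stiffness scale.

        Very soft walls (C of order 0.01 kPa) make the cold-start tangent
        nearly singular.  The full load is first equilibrated with the
        passive stiffness scaled up by s (found adaptively), then s is walked
        back to 1 geometrically, re-converging by damped Newton at each step.
        """
        base_C = self.C_elem.copy()
        info = SolveInfo()
        try:
            s = 4.0
            while True:
                self.C_elem = base_C * s
                try:
                    u, inf0 = self.solve(
                        None, p_lv, p_rv, 0.0, n_steps=n_steps, tol=tol
                    )
                    info.load_steps += inf0.load_steps
                    info.newton_iterations += inf0.newton_iterations
                    break
                except NonConvergenceError:
                    s *= 4.0
                    if s > 1.0e6:
                        raise
            fref = self._external_norm(p_lv, p_rv, u)
            while s > 1.0 + 1e-9:
                s_try = max(1.0, 0.5 * s)
                while True:
                    self.C_elem = base_C * s_try
                    res, its, rn = self.newton(u, p_lv, p_rv, 0.0, tol, 30, fref)
                    info.newton_iterations += its
                    if res is not None:
                        u, s = res, s_try
                        info.load_steps += 1
                        info.residual_norm = rn
                        break
                    s_try = np.sqrt(s * s_try)       # smaller reduction
                    info.bisections += 1
                    if s / s_try < 1.0005:
                        raise NonConvergenceError(
                            f"stiffness homotopy stalled at scale {s:.4g}"
                        )
            return u, info
        finally:
            self.C_elem = base_C

    def _external_norm(self, p_lv: float, p_rv: float, u: np.ndarray) -> float:
        x = self.mesh.nodes + u.reshape(-1, 3)
        f = np.zeros(self.n_dof)
        for name, p in (("endo", p_lv), ("septal_epi", p_rv)):
            if p != 0.0 and name in self.facets:
                fv, _ = self._pressure_terms(x, name, p)
                f += fv
        return np.linalg.norm(f)
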