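"""Myocardial constitutive laws and CMR-score-driven parameter maps.

Passive myocardium follows the transversely isotropic Fung-type exponential
law of Guccione and co-workers,

    W = C/2 (exp(Q) - 1),
    Q = b_f E11^2 + b_t (E22^2 + E33^2 + E23^2 + E32^2)
        + b_fs (E12^2 + E21^2 + E13^2 + E31^2),

with E the Green-Lagrange strain in the local fiber frame (1 = fiber,
2 = cross-fiber in plane, 3 = radial).  Near-incompressibility is enforced
with a volumetric penalty U(J) = kappa/2 (J - 1)^2.

Active contraction uses a time-varying elastance model evaluated at end
systole: the fiber tension is

    T0 = Tmax * Ca0^2 / (Ca0^2 + ECa50^2) * Ct,

with the length-dependent calcium sensitivity
ECa50 = Ca0max / sqrt(exp(B (l - l0)) - 1) and sarcomere length
l = lR sqrt(2 E11 + 1).  Ct is held at its end-systolic peak value.

Regional disease enters through two 17-sector maps: passive stiffness
scales with the late-gadolinium-enhancement (LGE, 0-4) score,

    C_n = C_H (1 + 9 LGE_n / 4),

and contractility with both LGE and the stress-perfusion (SP, 0-3) score via
the ischemia-effect parameter alpha in [0, 1],

    Tmax_n = Tmax_H (1 - LGE_n/4) (1 - alpha SP_n/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PassiveLaw",
    "ActiveLaw",
    "StrainTensorFiberFrame",
    "ScoreMap17",
    "GlobalParameters",
    "SectorParameters",
    "MechanicsError",
    "passive_stiffness_map",
    "contractility_map",
    "strain_energy",
    "passive_stress",
    "active_stress",
    "active_tension_and_slope",
]


class MechanicsError(RuntimeError):
    """Non-physical kinematic input (e.g. non-invertible deformation)."""


@dataclass(frozen=True)
class PassiveLaw:
    """Guccione exponential law plus volumetric penalty (stresses in kPa)."""

    C: float = 0.2
    b_f: float = 49.25
    b_t: float = 19.25
    b_fs: float = 17.44
    kappa: float = 1.0e3

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("stiffness scale C must be positive")
        if self.kappa < 100.0 * self.C:
            raise ValueError("volumetric modulus kappa must be >= 100 C")

    @property
    def exponent_matrix(self) -> np.ndarray:
        """Q = sum_ij B_ij E_ij^2 in the fiber frame."""
        bf, bt, bfs = self.b_f, self.b_t, self.b_fs
        return np.array([[bf, bfs, bfs], [bfs, bt, bt], [bfs, bt, bt]])


@dataclass(frozen=True)
class ActiveLaw:
    """End-systolic time-varying elastance parameters.

    Calcium constants follow the elastance-model lineage the passive law comes
    from; all are configurable.  ``Ct_ES`` is the activation variable at end
    systole (peak contraction = 1).  ``crossfiber_fraction`` adds the given
    fraction of the fiber tension transversely (0 = fiber-only, the default).
    """

    Tmax: float | None = None       # kPa; usually supplied per sector instead
    Ca0: float = 4.35               # umol/L
    Ca0max: float = 4.35            # umol/L
    B: float = 4.75                 # 1/um
    l0: float = 1.58                # um, length below which tension vanishes
    lR: float = 1.85                # um, slack sarcomere length
    Ct_ES: float = 1.0
    crossfiber_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.Ct_ES <= 1.0:
            raise ValueError("Ct_ES must lie in [0, 1]")
        if self.lR <= self.l0:
            raise ValueError("slack length lR must exceed l0")
        if self.Tmax is not None and self.Tmax < 0:
            raise ValueError("Tmax must be non-negative")


@dataclass
class StrainTensorFiberFrame:
    """Symmetric Green-Lagrange strain in the fiber frame (dimensionless)."""

    E11: float = 0.0
    E22: float = 0.0
    E33: float = 0.0
    E12: float = 0.0
    E13: float = 0.0
    E23: float = 0.0

    @property
    def tensor(self) -> np.ndarray:
        e = self
        return np.array(
            [[e.E11, e.E12, e.E13], [e.E12, e.E22, e.E23], [e.E13, e.E23, e.E33]]
        )


def _as_tensor(E) -> np.ndarray:
    if isinstance(E, StrainTensorFiberFrame):
        return E.tensor
    E = np.asarray(E, dtype=float)
    if E.shape != (3, 3) or not np.allclose(E, E.T):
        raise ValueError("strain must be a symmetric 3x3 tensor")
    return E


# ---------------------------------------------------------------------------
# score maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreMap17:
    """Per-sector LGE (0-4) and SP (0-3) scores, sectors 1-17."""

    lge: np.ndarray
    sp: np.ndarray

    def __post_init__(self) -> None:
        lge = np.asarray(self.lge, dtype=int)
        sp = np.asarray(self.sp, dtype=int)
        object.__setattr__(self, "lge", lge)
        object.__setattr__(self, "sp", sp)
        if lge.shape != (17,) or sp.shape != (17,):
            raise ValueError("score maps need exactly 17 sectors")
        if lge.min() < 0 or lge.max() > 4:
            raise ValueError("LGE scores must be integers in 0..4")
        if sp.min() < 0 or sp.max() > 3:
            raise ValueError("SP scores must be integers in 0..3")

    @classmethod
    def zeros(cls) -> "ScoreMap17":
        return cls(np.zeros(17, dtype=int), np.zeros(17, dtype=int))

    @classmethod
    def from_csv(cls, path) -> "ScoreMap17":
        df = pd.read_csv(path)
        df = df.sort_values("sector")
        return cls(df["lge"].to_numpy(), df["sp"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"sector": np.arange(1, 18), "lge": self.lge, "sp": self.sp}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class GlobalParameters:
    """The three estimated quantities plus the objective volume weight."""

    C_H: float
    Tmax_H: float
    alpha: float
    W_vol: float = 10.0

    def __post_init__(self) -> None:
        if self.C_H <= 0:
            raise ValueError("C_H must be positive")
        if self.Tmax_H < 0:
            raise ValueError("Tmax_H must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.W_vol < 0:
            raise ValueError("W_vol must be non-negative")


@dataclass(frozen=True)
class SectorParameters:
    """Per-sector stiffness and contractility derived from the score maps."""

    C_n: np.ndarray
    Tmax_n: np.ndarray

    @classmethod
    def from_scores(
        cls, params: GlobalParameters, scores: ScoreMap17
    ) -> "SectorParameters":
        return cls(
            passive_stiffness_map(params.C_H, scores),
            contractility_map(params.Tmax_H, params.alpha, scores),
        )


def passive_stiffness_map(C_H: float, scores: ScoreMap17) -> np.ndarray:
    """Sector stiffness C_n = C_H (1 + 9 LGE_n / 4); a transmural infarct
    (LGE = 4) is ten times stiffer than healthy tissue."""
    if C_H <= 0:
        raise ValueError("C_H must be positive")
    return C_H * (1.0 + 9.0 * scores.lge / 4.0)


def contractility_map(Tmax_H: float, alpha: float, scores: ScoreMap17) -> np.ndarray:
    """Sector contractility Tmax_n = Tmax_H (1 - LGE_n/4)(1 - alpha SP_n/3)."""
    if Tmax_H < 0:
        raise ValueError("Tmax_H must be non-negative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return Tmax_H * (1.0 - scores.lge / 4.0) * (1.0 - alpha * scores.sp / 3.0)


# ---------------------------------------------------------------------------
# pointwise stress evaluation (fiber frame)
# ---------------------------------------------------------------------------

def strain_energy(E, law: PassiveLaw) -> float:
    """Total strain-energy density W(E) + U(J) (kPa) for fiber-frame strain."""
    E = _as_tensor(E)
    C = 2.0 * E + np.eye(3)
    detC = np.linalg.det(C)
    if detC <= 0 or np.linalg.eigvalsh(C).min() <= 0:
        raise MechanicsError("2E + I must be positive definite")
    B = law.exponent_matrix
    Q = float(np.sum(B * E * E))
    J = np.sqrt(detC)
    return 0.5 * law.C * (np.exp(Q) - 1.0) + 0.5 * law.kappa * (J - 1.0) ** 2


def passive_stress(E, law: PassiveLaw, J: float | None = None) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = dW/dE + kappa (J-1) J C^-1 (kPa).

    ``E`` is the Green-Lagrange strain in the fiber frame.  If ``J`` is not
    given it is taken from E via J = sqrt(det(2E + I)).
    """
    E = _as_tensor(E)
    Cg = 2.0 * E + np.eye(3)
    detC = np.linalg.det(Cg)
    if detC <= 0 or np.linalg.eigvalsh(Cg).min() <= 0:
        raise MechanicsError("2E + I must be positive definite")
    B = law.exponent_matrix
    Q = float(np.sum(B * E * E))
    S = law.C * np.exp(Q) * (B * E)
    if J is None:
        J = np.sqrt(detC)
    S = S + law.kappa * (J - 1.0) * J * np.linalg.inv(Cg)
    return 0.5 * (S + S.T)


def active_tension_and_slope(E11, Tmax, law: ActiveLaw):
    """Fiber tension T0(E11) and its derivative dT0/dE11, vectorized.

    The tension is clamped to zero once the sarcomere shortens to l0; the
    clamp is logged at debug level because it usually marks strongly
    shortening regions during continuation.
    """
    E11 = np.asarray(E11, dtype=float)
    Tmax = np.asarray(Tmax, dtype=float)
    stretch_sq = np.maximum(2.0 * E11 + 1.0, 1e-12)
    l = law.lR * np.sqrt(stretch_sq)
    active = l > law.l0
    if not np.all(active):
        logger.debug("active tension clamped to 0 for %d points with l <= l0",
                     int(np.sum(~active)))
    # exp(B dl) - 1, clamped: beyond ~l0 + 12/B the sensitivity saturates anyway
    x = np.expm1(np.minimum(law.B * np.maximum(l - law.l0, 0.0), 60.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            active, law.Ca0**2 * x / (law.Ca0**2 * x + law.Ca0max**2), 0.0
        )
        dfrac_dx = np.where(
            active,
            law.Ca0**2 * law.Ca0max**2 / (law.Ca0**2 * x + law.Ca0max**2) ** 2,
            0.0,
        )
    T0 = Tmax * law.Ct_ES * frac
    dl_dE = law.lR**2 / l
    dx_dl = law.B * (x + 1.0)
    dT0 = np.where(active, Tmax * law.Ct_ES * dfrac_dx * dx_dl * dl_dE, 0.0)
    return T0, dT0


def active_stress(E11: float, Tmax_n: float, law: ActiveLaw) -> float:
    """End-systolic active fiber tension T0 (kPa) at fiber strain E11."""
    if Tmax_n < 0:
        raise ValueError("Tmax_n must be non-negative")
    T0, _ = active_tension_and_slope(float(E11), float(Tmax_n), law)
    return float(T0)
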