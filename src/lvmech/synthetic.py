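"""Synthetic test-case generation and printed clinical fixtures.

The synthetic workflow mirrors method verification with manufactured data:
a forward model with *known* (C_H, Tmax_H, alpha) produces per-sector
end-systolic strains and volumes, those become the "experimental" targets,
and the inverse machinery must recover the ground truth.  Fixtures carry the
published per-subject pressures (five FMR patients plus a healthy volunteer)
and 17-segment LGE/SP/wall-motion score maps; the volunteer's LGE and SP
scores are zero by definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .case import Case
from .geometry import IdealizedGeometry, MeshDensity
from .materials import GlobalParameters, ScoreMap17
from .mechanics import PressureSet, StrainTable
from .revasc import WallMotionScores

__all__ = [
    "SUBJECT_IDS",
    "SyntheticCase",
    "make_synthetic_case",
    "load_fixture",
    "case_from_fixture",
]

SUBJECT_IDS = (
    "patient1", "patient2", "patient3", "patient4", "patient5", "volunteer",
)


def _data(name: str) -> pd.DataFrame:
    with resources.files("lvmech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fixture(subject_id: str):
    """Printed pressures and score maps for one subject.

    Returns ``(PressureSet, ScoreMap17, WallMotionScores)``; raises
    ``KeyError`` for an unknown id.
    """
    if subject_id not in SUBJECT_IDS:
        raise KeyError(
            f"unknown subject {subject_id!r}; expected one of {SUBJECT_IDS}"
        )
    prow = _data("pressures.csv").set_index("subject").loc[subject_id]
    pressures = PressureSet(
        float(prow["lv_edp"]), float(prow["lv_esp"]),
        float(prow["rv_edp"]), float(prow["rv_esp"]), ef=float(prow["ef"]),
    )
    srows = _data("scores.csv").query("subject == @subject_id").sort_values("segment")
    scores = ScoreMap17(srows["lge"].to_numpy(), srows["sp"].to_numpy())
    wm = WallMotionScores(srows["wm_bl"].to_numpy(), srows["wm_fu"].to_numpy())
    return pressures, scores, wm


@dataclass
class SyntheticCase(Case):
    """A forward problem with known ground truth and optional strain noise.

    ``sigma_strain`` is the standard deviation of i.i.d. Gaussian noise added
    to the target E_cc/E_ll (dimensionless strain); the published synthetic
    verification used noiseless targets, so the default is 0.
    """

    truth: GlobalParameters = field(
        default_factory=lambda: GlobalParameters(0.2, 350.0, 0.0)
    )
    sigma_strain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_strain < 0:
            raise ValueError("sigma_strain must be non-negative")


def case_from_fixture(
    subject_id: str,
    truth: GlobalParameters,
    geometry: IdealizedGeometry | None = None,
    density: MeshDensity | None = None,
    **kw,
) -> SyntheticCase:
    """Synthetic case using a subject's printed pressures and score map."""
    pressures, scores, _ = load_fixture(subject_id)
    return SyntheticCase(
        geometry=geometry or IdealizedGeometry(),
        density=density or MeshDensity(),
        pressures=pressures,
        scores=scores,
        truth=truth,
        **kw,
    )


def apply_strain_noise(
    table: StrainTable, sigma: float, rng: np.random.Generator
) -> StrainTable:
    """Independent Gaussian perturbation of E_cc and E_ll (not E_rr/volumes)."""
    return StrainTable(
        table.e_cc + rng.normal(0.0, sigma, 17),
        table.e_ll + rng.normal(0.0, sigma, 17),
        table.e_rr,
        table.edv,
        table.esv,
    )


def make_synthetic_case(
    case: SyntheticCase,
    out_targets=None,
    out_truth=None,
    runner=None,
):
    """Forward-simulate the ground truth into an "experimental" target table.

    Returns ``(targets, truth_record)``.  The ground truth is kept in a
    separate record (and optional sidecar JSON) so estimation code consuming
    the targets cannot accidentally read it.  With the same seed the noised
    table is bit-identical across calls.
    """
    runner = runner or case.runner()
    t = case.truth
    targets = runner.strain_table(t.C_H, t.Tmax_H, t.alpha)
    if case.sigma_strain > 0.0:
        rng = np.random.default_rng(case.seed)
        targets = apply_strain_noise(targets, case.sigma_strain, rng)
    truth_record = {
        "C_H": t.C_H,
        "Tmax_H": t.Tmax_H,
        "alpha": t.alpha,
        "EDV_ml": targets.edv,
        "ESV_ml": targets.esv,
        "sigma_strain": case.sigma_strain,
        "seed": case.seed,
    }
    if out_targets is not None:
        targets.to_csv(out_targets)
    if out_truth is not None:
        with open(out_truth, "w") as fh:
            json.dump(truth_record, fh, indent=1)
    return targets, truth_record
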