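"""Shared fixtures: meshes and forward/inverse results reused across tests.

The expensive objects (meshes, converged solves, recovery runs) are session
scoped so the suite pays for each forward/inverse computation once.
"""

from __future__ import annotations

import pytest

import lvmech as lm
from lvmech.case import build_mesh
from lvmech.inverse import ObjectiveSpec, calibrate_CH, optimize_contractility
from lvmech.synthetic import case_from_fixture, make_synthetic_case

# test-scale mesh density: fine enough to populate all 17 sectors with a few
# elements each, coarse enough that a full optimization run stays at desk scale
CI_DENSITY = lm.MeshDensity(2, 12, 6)

PATIENT2_TRUTH = dict(C_H=0.192, Tmax_H=336.8)   # published optimized values
PATIENT5_TRUTH = dict(C_H=0.0094, Tmax_H=401.4)


@pytest.fixture(scope="session")
def mesh_ci():
    """Reference idealized mesh: labeled, fibered, septum from ray casting."""
    return build_mesh(lm.IdealizedGeometry(), CI_DENSITY)


@pytest.fixture(scope="session")
def healthy_forward():
    """Volunteer-pressure healthy forward solve (ED + ES + strain table)."""
    case = case_from_fixture(
        "volunteer", lm.GlobalParameters(0.2, 300.0, 0.0), density=CI_DENSITY
    )
    runner = case.runner()
    ed = runner.ed_state(0.2)
    es = runner.es_state(0.2, 300.0, 0.0)
    table = runner.strain_table(0.2, 300.0, 0.0)
    return runner, ed, es, table


@pytest.fixture(scope="session")
def p2_recovery():
    """Synthetic parameter-recovery runs: patient 2 scores/pressures,
    ground-truth alpha in {0, 1}, three optimizer initial guesses each."""
    guesses = [(100.0, 0.0), (350.0, 0.5), (600.0, 1.0)]
    out = {"truth": PATIENT2_TRUTH, "runs": []}
    for alpha_true in (0.0, 1.0):
        case = case_from_fixture(
            "patient2",
            lm.GlobalParameters(PATIENT2_TRUTH["C_H"], PATIENT2_TRUTH["Tmax_H"],
                                alpha_true),
            density=CI_DENSITY,
        )
        runner = case.runner()
        targets, _ = make_synthetic_case(case, runner=runner)
        spec = ObjectiveSpec(targets)
        for init in guesses:
            res = optimize_contractility(
                runner, PATIENT2_TRUTH["C_H"], spec, init=init
            )
            out["runs"].append(
                {"alpha_true": alpha_true, "init": init, "result": res,
                 "targets": targets}
            )
        out.setdefault("runners", {})[alpha_true] = runner
        out.setdefault("targets", {})[alpha_true] = targets
    return out


@pytest.fixture(scope="session")
def two_stage_results(p2_recovery):
    """Full two-stage (C_H calibration + contractility) fits for two cases."""
    results = []
    # patient 2, alpha* = 1: reuse the recovery runner/targets
    runner2 = p2_recovery["runners"][1.0]
    targets2 = p2_recovery["targets"][1.0]
    ch2 = calibrate_CH(runner2, targets2.edv)
    res2 = optimize_contractility(runner2, ch2, ObjectiveSpec(targets2),
                                  init=(350.0, 0.5))
    results.append({"case": "patient2", "truth_C_H": PATIENT2_TRUTH["C_H"],
                    "targets": targets2, "result": res2})
    # patient 5, alpha* = 1: soft-wall case exercised end to end
    case5 = case_from_fixture(
        "patient5",
        lm.GlobalParameters(PATIENT5_TRUTH["C_H"], PATIENT5_TRUTH["Tmax_H"], 1.0),
        density=CI_DENSITY,
    )
    runner5 = case5.runner()
    targets5, _ = make_synthetic_case(case5, runner=runner5)
    ch5 = calibrate_CH(runner5, targets5.edv)
    res5 = optimize_contractility(runner5, ch5, ObjectiveSpec(targets5),
                                  init=(350.0, 0.5))
    results.append({"case": "patient5", "truth_C_H": PATIENT5_TRUTH["C_H"],
                    "targets": targets5, "result": res5})
    return results
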