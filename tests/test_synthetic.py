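"""Synthetic cases and the printed clinical fixtures."""

import numpy as np
import pytest

import lvmech as lm
from lvmech.inverse import ObjectiveSpec, objective
from lvmech.materials import ScoreMap17
from lvmech.mechanics import StrainTable
from lvmech.revasc import WallMotionScores
from lvmech.synthetic import (
    SUBJECT_IDS,
    apply_strain_noise,
    case_from_fixture,
    load_fixture,
    make_synthetic_case,
)


class TestFixtures:
    def test_patient5_pressures_match_the_published_table(self):
        pressures, _, _ = load_fixture("patient5")
        assert (pressures.lv_edp, pressures.lv_esp) == (10, 140)
        assert (pressures.rv_edp, pressures.rv_esp) == (8, 40)

    def test_patient2_sector5_scores(self):
        _, scores, wm = load_fixture("patient2")
        assert scores.lge[4] == 3 and scores.sp[4] == 3
        assert wm.wm_bl[4] == 4 and wm.wm_fu[4] == 2

    def test_volunteer_is_disease_free(self):
        _, scores, wm = load_fixture("volunteer")
        assert (scores.lge == 0).all() and (scores.sp == 0).all()
        assert (wm.wm_bl == 0).all() and (wm.wm_fu == 0).all()

    def test_unknown_subject_raises(self):
        with pytest.raises(KeyError, match="unknown"):
            load_fixture("patient9")

    def test_all_subjects_load_and_validate(self):
        for sid in SUBJECT_IDS:
            pressures, scores, wm = load_fixture(sid)
            assert pressures.lv_esp > pressures.lv_edp
            assert scores.lge.shape == (17,)

    def test_score_map_csv_round_trip(self, tmp_path):
        _, scores, wm = load_fixture("patient3")
        p = tmp_path / "scores.csv"
        scores.to_csv(p)
        back = ScoreMap17.from_csv(p)
        assert np.array_equal(back.lge, scores.lge)
        assert np.array_equal(back.sp, scores.sp)
        q = tmp_path / "wm.csv"
        wm.to_csv(q)
        back_wm = WallMotionScores.from_csv(q)
        assert np.array_equal(back_wm.wm_bl, wm.wm_bl)
        assert np.array_equal(back_wm.wm_fu, wm.wm_fu)

    def test_strain_table_csv_round_trip(self, tmp_path):
        t = StrainTable(
            np.linspace(-0.2, 0, 17), np.linspace(-0.1, 0.05, 17),
            np.linspace(0, 0.4, 17), 123.4, 87.6,
        )
        p = tmp_path / "targets.csv"
        t.to_csv(p)
        back = StrainTable.from_csv(p)
        assert np.allclose(back.e_cc, t.e_cc)
        assert np.allclose(back.e_rr, t.e_rr)
        assert back.edv == t.edv and back.esv == t.esv


class TestNoise:
    def zero_table(self):
        return StrainTable(np.zeros(17), np.zeros(17), np.zeros(17), 100.0, 50.0)

    def test_empirical_noise_sd_matches_sigma(self):
        sigma = 0.03
        rng = np.random.default_rng(7)
        draws = []
        for _ in range(300):
            t = apply_strain_noise(self.zero_table(), sigma, rng)
            draws.extend(t.e_cc)
            draws.extend(t.e_ll)
        sd = np.std(draws)
        assert abs(sd - sigma) / sigma < 0.05
        assert len(draws) >= 10_000

    def test_noise_leaves_radial_strain_and_volumes_untouched(self):
        rng = np.random.default_rng(3)
        t = apply_strain_noise(self.zero_table(), 0.05, rng)
        assert np.all(t.e_rr == 0.0)
        assert (t.edv, t.esv) == (100.0, 50.0)

    def test_same_seed_reproduces_the_same_noised_table(self):
        t1 = apply_strain_noise(self.zero_table(), 0.02, np.random.default_rng(11))
        t2 = apply_strain_noise(self.zero_table(), 0.02, np.random.default_rng(11))
        assert np.array_equal(t1.e_cc, t2.e_cc)
        assert np.array_equal(t1.e_ll, t2.e_ll)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            case_from_fixture(
                "patient1", lm.GlobalParameters(0.2, 300.0, 0.5), sigma_strain=-0.1
            )


class TestRoundTrip:
    def test_noiseless_targets_give_zero_objective_at_ground_truth(
        self, p2_recovery
    ):
        runner = p2_recovery["runners"][1.0]
        targets = p2_recovery["targets"][1.0]
        truth = p2_recovery["truth"]
        model = runner.strain_table(truth["C_H"], truth["Tmax_H"], 1.0)
        assert objective(model, ObjectiveSpec(targets)) == 0.0

    def test_truth_record_mirrors_the_case(self, tmp_path):
        import json
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            case = case_from_fixture(
                "volunteer", lm.GlobalParameters(0.25, 280.0, 0.0),
                density=lm.MeshDensity(1, 8, 4),
            )
            targets, record = make_synthetic_case(
                case,
                out_targets=tmp_path / "t.csv",
                out_truth=tmp_path / "truth.json",
            )
        assert record["C_H"] == 0.25 and record["Tmax_H"] == 280.0
        sidecar = json.loads((tmp_path / "truth.json").read_text())
        assert sidecar["ESV_ml"] == pytest.approx(targets.esv)
        back = StrainTable.from_csv(tmp_path / "t.csv")
        assert np.allclose(back.e_cc, targets.e_cc)
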