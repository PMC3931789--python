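"""Interface/contact bookkeeping, CAPRI quality classes, decoy statistics,
funnel analysis, SASA and the relative-accessibility success predictor."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pairdock.errors import ValidationError
from pairdock.evaluation import (
    a_rel,
    assess_quality,
    classifier_metrics,
    classify_difficulty,
    classify_quality,
    contacts,
    decoy_set_metrics,
    expected_sasa,
    funnel_spearman,
    interface_residues,
    predict_success,
    random_baseline,
    sasa,
)
from pairdock.structure import Pose, apply_pose
from conftest import simple_structure


def _residue_pair(distance):
    a = simple_structure([[0, 0, 0]], names=["CB"], resnames=["ALA"])
    b = simple_structure([[distance, 0, 0]], names=["CB"], resnames=["ALA"], chain="B")
    return a, b


class TestInterfaceAndContacts:
    def test_far_partners_have_empty_sets(self):
        a, b = _residue_pair(50.0)
        rec, lig = interface_residues(a, b)
        assert rec == set() and lig == set()
        assert contacts(a, b) == set()

    def test_ten_angstrom_interface_rule(self):
        a, b = _residue_pair(9.5)
        rec, lig = interface_residues(a, b)
        assert rec == {("A", 1, "")} and lig == {("B", 1, "")}

    @pytest.mark.parametrize("d,expected", [(4.9, 1), (5.1, 0)])
    def test_five_angstrom_contact_boundary(self, d, expected):
        a, b = _residue_pair(d)
        assert len(contacts(a, b)) == expected

    def test_matches_brute_force_residue_scan(self, toy_complex):
        rec, lig = toy_complex
        got_rec, got_lig = interface_residues(rec, lig)
        got_contacts = contacts(rec, lig)
        exp_rec, exp_lig, exp_contacts = set(), set(), set()
        rk = [( str(rec.chain[i]), int(rec.residue_number[i]), str(rec.insertion_code[i]))
              for i in range(len(rec))]
        lk = [( str(lig.chain[j]), int(lig.residue_number[j]), str(lig.insertion_code[j]))
              for j in range(len(lig))]
        for i in range(len(rec)):
            for j in range(len(lig)):
                d = np.linalg.norm(rec.coords[i] - lig.coords[j])
                if d < 10.0:
                    exp_rec.add(rk[i])
                    exp_lig.add(lk[j])
                if d < 5.0:
                    exp_contacts.add((rk[i], lk[j]))
        assert got_rec == exp_rec and got_lig == exp_lig
        assert got_contacts == exp_contacts


class TestQualityClassification:
    @pytest.mark.parametrize("f_nat,l_rmsd,i_rmsd,expected", [
        (1.0, 0.0, 0.0, "high"),
        (0.05, 3.0, 1.0, "incorrect"),   # too few native contacts
        (0.2, 12.0, 3.0, "acceptable"),  # printed worked boundary case
        (0.4, 4.0, 1.5, "medium"),
        (0.6, 2.0, 1.5, "medium"),       # high f_nat but displaced
        (0.35, 7.0, 3.0, "acceptable"),
        (0.05, 20.0, 10.0, "incorrect"),
    ])
    def test_reference_cases(self, f_nat, l_rmsd, i_rmsd, expected):
        assert classify_quality(f_nat, l_rmsd, i_rmsd) == expected

    def test_dense_sweep_fires_exactly_one_class(self):
        # precedence high > medium > acceptable > incorrect resolves the
        # printed criteria's double-assigned boundaries; the four predicates
        # must cover the whole domain
        f_vals = np.concatenate([np.linspace(0, 1, 21), [0.1, 0.3, 0.5]])
        r_vals = np.concatenate([np.linspace(0, 12, 13), [1.0, 2.0, 4.0, 5.0, 10.0]])
        for f, l, i in itertools.product(f_vals, r_vals, r_vals):
            high = f >= 0.5 and (l <= 1.0 or i <= 1.0)
            medium = ((0.3 <= f <= 0.5) and (l <= 5.0 or i <= 2.0)) or (
                f > 0.5 and l > 1.0 and i > 1.0)
            acceptable = ((0.1 <= f <= 0.3) and (l <= 10.0 or i <= 4.0)) or (
                f > 0.3 and l > 5.0 and i > 2.0)
            incorrect = f < 0.1 or (l > 10.0 and i > 4.0)
            fired = [high, medium, acceptable, incorrect]
            assert any(fired), (f, l, i)
            expected = ("high", "medium", "acceptable", "incorrect")[fired.index(True)]
            assert classify_quality(f, l, i) == expected

    def test_identity_prediction_is_high(self, toy_complex):
        rec, lig = toy_complex
        rep = assess_quality((rec, lig), (rec, lig))
        assert rep.f_nat == 1.0 and rep.f_not == 0.0
        assert rep.i_rmsd == pytest.approx(0.0, abs=1e-6)
        assert rep.l_rmsd == pytest.approx(0.0, abs=1e-6)
        assert rep.quality_class == "high"

    def test_far_prediction_is_incorrect(self, toy_complex):
        rec, lig = toy_complex
        moved = apply_pose(lig, Pose(np.eye(3), np.array([40.0, 0, 0])))
        rep = assess_quality((rec, moved), (rec, lig))
        assert rep.quality_class == "incorrect"
        assert rep.f_nat == 0.0

    def test_multiple_binding_modes_reports_matching_mode(self, toy_complex):
        rec, lig = toy_complex
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mode2_lig = apply_pose(lig, Pose(rot, np.array([12.0, 0, 0])))
        rep = assess_quality((rec, mode2_lig), [(rec, lig), (rec, mode2_lig)])
        assert rep.reference_mode == 1
        assert rep.quality_class == "high"

    def test_rigidly_moved_complex_still_high(self, toy_complex):
        # quality must be invariant to the frame of the prediction
        rec, lig = toy_complex
        rot = Rotation.from_euler("xyz", [15, 25, -35], degrees=True).as_matrix()
        pose = Pose(rot, np.array([4.0, 5.0, -6.0]))
        rep = assess_quality((apply_pose(rec, pose), apply_pose(lig, pose)),
                             (rec, lig))
        assert rep.quality_class == "high"
        assert rep.l_rmsd == pytest.approx(0.0, abs=1e-6)


class TestDifficulty:
    def test_identical_unbound_is_easy(self, toy_complex):
        assert classify_difficulty(toy_complex, toy_complex) == "easy"

    @staticmethod
    def _deform(toy_complex, scale, seed=0):
        rec, lig = toy_complex
        rng = np.random.default_rng(seed)
        drec = rec.with_coords(rec.coords + rng.normal(scale=scale, size=rec.coords.shape))
        dlig = lig.with_coords(lig.coords + rng.normal(scale=scale, size=lig.coords.shape))
        return drec, dlig

    def test_deformed_interface_is_difficult(self, toy_complex):
        unbound = self._deform(toy_complex, 2.0)
        assert classify_difficulty(toy_complex, unbound) == "difficult"

    def test_moderate_deformation_is_medium(self, toy_complex):
        unbound = self._deform(toy_complex, 1.0)
        assert classify_difficulty(toy_complex, unbound) == "medium"


class TestDecoyMetrics:
    def test_all_rank1_hits(self):
        stats = decoy_set_metrics([[4.0] + [30.0] * 9] * 7)
        assert stats.best_rmsd == 100.0 and stats.r5 == 100.0 and stats.r10 == 100.0

    def test_no_hits_anywhere(self):
        stats = decoy_set_metrics([[30.0] * 10] * 5)
        assert (stats.r5, stats.r10, stats.n10, stats.best_rmsd) == (0, 0, 0, 0)

    def test_hand_counted_ensemble(self):
        targets = [
            [3.0, 8.0, 9.0, 20.0, 20.0],   # 3 of top5 < 10 -> n10, best, r5, r10
            [8.0, 20.0, 20.0, 20.0, 20.0], # 1 hit -> best, r10
            [20.0] * 5,                    # nothing
            [4.0, 4.5, 20.0, 20.0, 20.0],  # 2 hits -> best, r5, r10
        ]
        stats = decoy_set_metrics(targets)
        assert stats.n10 == pytest.approx(25.0)
        assert stats.best_rmsd == pytest.approx(75.0)
        assert stats.r5 == pytest.approx(50.0)
        assert stats.r10 == pytest.approx(75.0)


class TestRandomBaseline:
    @pytest.mark.parametrize("p,n,k,pct", [
        (0.28, 5, 1, 81),
        (0.28, 5, 3, 14),
        (0.19, 10, 1, 88),
    ])
    def test_printed_baselines(self, p, n, k, pct):
        assert random_baseline(p, n, k).percent == pct

    def test_certainty(self):
        assert random_baseline(1.0, 7, 3).probability == pytest.approx(1.0)
        assert random_baseline(1.0, 7, 3).percent == 100

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(12345)
        n_draws = 100000
        for p, n, k in [(0.28, 5, 1), (0.28, 5, 3), (0.19, 10, 1), (0.5, 8, 4)]:
            hits = (rng.random((n_draws, n)) < p).sum(axis=1)
            mc = float((hits >= k).mean())
            exact = random_baseline(p, n, k).probability
            se = math.sqrt(exact * (1 - exact) / n_draws)
            assert abs(mc - exact) <= 3 * se + 1e-12

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            random_baseline(1.2, 5, 1)


class TestFunnel:
    def test_perfect_monotone_is_one(self):
        scores = [-5.0, -4.0, -3.0, -2.0]
        rmsds = [1.0, 2.0, 5.0, 9.0]
        assert funnel_spearman(scores, rmsds).spearman_rs == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert funnel_spearman([1, 2, 3, 4], [9, 7, 5, 2]).spearman_rs == pytest.approx(-1.0)

    def test_matches_rank_transform_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        rmsds = rng.normal(size=40)
        # independent implementation: Pearson on average ranks
        def ranks(x):
            order = np.argsort(x)
            r = np.empty(len(x))
            r[order] = np.arange(1, len(x) + 1)
            return r
        ra, rb = ranks(scores), ranks(rmsds)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert funnel_spearman(scores, rmsds).spearman_rs == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=25)
        rmsds = rng.uniform(0.1, 20, size=25)
        base = funnel_spearman(scores, rmsds).spearman_rs
        assert funnel_spearman(np.exp(scores), rmsds ** 3).spearman_rs == pytest.approx(base)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            funnel_spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        st = simple_structure([[0, 0, 0]])  # carbon, r=1.7
        area = sasa(st, probe=1.4, n_points=960)
        expected = 4 * math.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.005)

    def test_distant_atoms_are_additive(self):
        st = simple_structure([[0, 0, 0], [100, 0, 0]])
        single = sasa(simple_structure([[0, 0, 0]]))
        assert sasa(st) == pytest.approx(2 * single, rel=1e-9)

    def test_overlapping_pair_matches_dense_sampling(self):
        st = simple_structure([[0, 0, 0], [2.0, 0, 0]])
        coarse = sasa(st, n_points=960)
        dense = sasa(st, n_points=20000)
        assert coarse == pytest.approx(dense, rel=0.01)

    def test_convergence_on_doubling(self, toy_complex):
        _, lig = toy_complex
        a1 = sasa(lig, n_points=960)
        a2 = sasa(lig, n_points=1920)
        assert abs(a2 - a1) / a1 < 0.005

    def test_unknown_element_rejected(self):
        st = simple_structure([[0, 0, 0]], elements=["ZZ"])
        with pytest.raises(ValidationError):
            sasa(st)

    def test_matches_independent_implementation(self, toy_complex):
        # cross-check against biotite's Shrake-Rupley with the same radii
        import biotite.structure as struc
        _, lig = toy_complex
        mine = sasa(lig, probe=1.4, n_points=1920)
        arr = struc.AtomArray(len(lig))
        arr.coord = lig.coords.astype(np.float32)
        arr.chain_id = np.array([str(c) for c in lig.chain])
        arr.res_id = lig.residue_number
        arr.res_name = np.array([str(r) for r in lig.residue_name])
        arr.atom_name = np.array([str(n) for n in lig.name])
        arr.element = np.array([str(e) for e in lig.element])
        vdw = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
        radii = np.array([vdw[str(e)] for e in lig.element], dtype=np.float32)
        ref = float(np.nansum(struc.sasa(arr, probe_radius=1.4,
                                         point_number=1920, vdw_radii=radii)))
        assert mine == pytest.approx(ref, rel=0.01)


class TestArel:
    def test_ratio_identity(self, toy_complex):
        _, lig = toy_complex
        area = sasa(lig)
        from pairdock.structure import molecular_weight
        coeff = area / molecular_weight(lig) ** 0.73
        rep = a_rel(lig, coeff=coeff)
        assert rep.a_rel == pytest.approx(1.0, rel=1e-9)

    def test_halving_expectation_doubles_ratio(self, toy_complex):
        _, lig = toy_complex
        base = a_rel(lig)
        halved = a_rel(lig, coeff=base.expected_sasa and 6.3 / 2)
        assert halved.a_rel == pytest.approx(2 * base.a_rel, rel=1e-9)

    def test_extended_conformer_has_larger_arel(self):
        compact = simple_structure([[i * 1.2, 0, 0] for i in range(12)])
        extended = simple_structure([[i * 6.0, 0, 0] for i in range(12)])
        assert a_rel(extended).a_rel > a_rel(compact).a_rel

    def test_zero_weight_rejected(self):
        with pytest.raises(ValidationError):
            expected_sasa(0.0)


class TestPredictSuccess:
    def test_decision_rule_on_threshold(self, toy_complex):
        rec, lig = toy_complex
        r = a_rel(rec).a_rel
        l = a_rel(lig).a_rel
        hi, lo = max(r, l), min(r, l)
        assert predict_success(rec, lig, threshold=hi * 1.01).prediction == "success"
        assert predict_success(rec, lig, threshold=(lo + hi) / 2).prediction == "failure"
        # strict inequality: a_rel exactly at the threshold predicts failure
        assert predict_success(rec, lig, threshold=hi).prediction == "failure"


class TestClassifierMetrics:
    def test_all_correct(self):
        sens, spec, acc = classifier_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_positives_all_missed(self):
        sens, spec, acc = classifier_metrics([0, 0, 0, 0], [1, 1, 0, 0])
        assert sens == 0.0 and spec == 1.0 and acc == 0.5

    def test_scripted_confusion_table(self):
        # 8 TP, 2 FN, 6 TN, 4 FP
        preds = [1] * 8 + [0] * 2 + [0] * 6 + [1] * 4
        outcomes = [1] * 10 + [0] * 10
        sens, spec, acc = classifier_metrics(preds, outcomes)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.6)
        assert acc == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            classifier_metrics([], [])
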