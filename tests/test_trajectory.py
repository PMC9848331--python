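"""Ensemble analytics: superposition, RMSD/RMSF, H-bond occupancies, alerts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from conpath_dms.trajectory import (
    AtomSelection,
    HBondCriteria,
    ResidueMap,
    SelectionError,
    StructuralMetrics,
    TrajectoryEnsemble,
    average_structure,
    contact_occupancy,
    detect_hbonds,
    hbond_occupancy,
    interaction_alert,
    native_interactions,
    rmsd_series,
    rmsf_profile,
    second_half_mean,
    structural_alert,
    superpose,
    water_bridge_occupancy,
)

from conftest import brute_force_min_rmsd


def make_ens(atoms, frames):
    """atoms: list of (chain, resid, resname, atom_name); frames: list of coord lists."""
    chains, resids, resnames, names = zip(*atoms)
    return TrajectoryEnsemble(
        coords=np.asarray(frames, dtype=float),
        atom_names=np.array(names, dtype=object),
        res_ids=np.array(resids),
        res_names=np.array(resnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
    )


def place_acceptor(donor, hydrogen, dist, angle_deg):
    """Coordinates of an acceptor at a given donor distance and donor-H-acceptor angle."""
    theta = np.radians(angle_deg)
    u = (hydrogen - donor) / np.linalg.norm(hydrogen - donor)
    h = np.linalg.norm(hydrogen - donor)
    v = np.array([0.0, 1.0, 0.0]) if abs(u[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    v = v - np.dot(v, u) * u
    v /= np.linalg.norm(v)
    r = h * np.cos(theta) + np.sqrt(dist**2 - (h * np.sin(theta)) ** 2)
    m = -np.cos(theta) * u + np.sin(theta) * v
    return hydrogen + r * m


# ---------------------------------------------------------------------------
# Superposition and RMSD/RMSF
# ---------------------------------------------------------------------------


class TestSuperpose:
    square = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0.5]])

    def test_identity_on_self(self):
        sup = superpose(self.square, self.square)
        assert sup.fit_rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_invariance(self):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = self.square @ rot.T + np.array([5.0, 0, 0])
        sup = superpose(moved, self.square)
        assert sup.fit_rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.transformed, self.square, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_rotation_search(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(6, 3)) * 2.0
        mobile = ref + rng.normal(size=(6, 3)) * 0.7
        sup = superpose(mobile, ref)
        oracle = brute_force_min_rmsd(mobile, ref, seed=seed)
        assert sup.fit_rmsd == pytest.approx(oracle, abs=1e-3)

    def test_single_displaced_atom_toy_matches_oracle(self):
        mobile = self.square.copy()
        mobile[3] += np.array([0.0, 0.0, 1.0])
        sup = superpose(mobile, self.square)
        assert sup.fit_rmsd == pytest.approx(brute_force_min_rmsd(mobile, self.square), abs=1e-3)

    def test_degenerate_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(SelectionError, match="collinear|degenerate"):
            superpose(line, line)
        with pytest.raises(SelectionError, match=">= 3"):
            superpose(self.square[:2], self.square[:2])


class TestRmsdSeries:
    def _static(self, n_frames=4):
        atoms = [("A", i // 1 + 1, "GLY", "CA") for i in range(5)]
        base = np.array([[0, 0, 0], [3.5, 1, 0], [7, 0, 1], [10.5, 1, 1], [14, 0, 0.5]], float)
        return make_ens(atoms, [base] * n_frames)

    def test_static_trajectory_is_zero(self):
        ens = self._static()
        sel = AtomSelection.parse("A:*:CA")
        assert rmsd_series(ens, sel, sel).max() == pytest.approx(0.0, abs=1e-10)

    def test_rigid_body_motion_is_zero(self):
        ens = self._static()
        coords = ens.coords.copy()
        for f in range(1, ens.n_frames):
            mat = Rotation.from_euler("xyz", [10 * f, -5 * f, 20 * f], degrees=True).as_matrix()
            coords[f] = coords[0] @ mat.T + f * np.array([1.0, -2.0, 0.5])
        moving = dataclasses.replace(ens, coords=coords)
        sel = AtomSelection.parse("A:*:CA")
        assert rmsd_series(moving, sel, sel).max() == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_atom_displacement(self):
        # fit atoms (residues 1-4) static => identity fit; the 2 measured atoms
        # each move 1 Å in frame 2 => RMSD exactly 1.0
        atoms = [("A", i + 1, "GLY", "CA") for i in range(4)] + [
            ("A", 5, "GLY", "CB"), ("A", 6, "GLY", "CB")]
        base = np.array(
            [[0, 0, 0], [3, 1, 0], [6, 0, 2], [9, 1, 1], [20, 0, 0], [25, 0, 0]], float)
        frame2 = base.copy()
        frame2[4] += [1, 0, 0]
        frame2[5] += [0, 1, 0]
        ens = make_ens(atoms, [base, frame2])
        out = rmsd_series(ens, AtomSelection.parse("A:1-4:CA"), AtomSelection.parse("A:5-6:CB"))
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(1.0, abs=1e-9)

    def test_second_half_mean_window(self):
        assert second_half_mean(np.array([0.0, 0.0, 2.0, 4.0])) == pytest.approx(3.0)


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        atoms = [("A", i + 1, "GLY", "CA") for i in range(4)]
        base = np.array([[0, 0, 0], [3, 1, 0], [6, 0, 2], [9, 1, 1]], float)
        prof = rmsf_profile(make_ens(atoms, [base] * 3), AtomSelection.parse("A:*:CA"))
        assert prof.max() == pytest.approx(0.0, abs=1e-12)

    def test_alternating_displacement_closed_form(self):
        # atom 5 alternates x0 +/- d with identity fit => RMSF exactly d
        d = 0.8
        atoms = [("A", i + 1, "GLY", "CA") for i in range(4)] + [("A", 5, "GLY", "CA")]
        base = np.array([[0, 0, 0], [3, 1, 0], [6, 0, 2], [9, 1, 1], [20, 0, 0]], float)
        frames = []
        for f in range(6):
            fr = base.copy()
            fr[4, 0] += d if f % 2 == 0 else -d
            frames.append(fr)
        prof = rmsf_profile(make_ens(atoms, frames), AtomSelection.parse("A:*:CA"),
                            fit_selection=AtomSelection.parse("A:1-4:CA"))
        assert prof.loc[5] == pytest.approx(d, abs=1e-9)
        assert prof.loc[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_frame_window_rejected(self):
        atoms = [("A", i + 1, "GLY", "CA") for i in range(4)]
        base = np.array([[0, 0, 0], [3, 1, 0], [6, 0, 2], [9, 1, 1]], float)
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_profile(make_ens(atoms, [base] * 5), AtomSelection.parse("A:*:CA"),
                         window=slice(0, 1))


class TestAverageStructure:
    def test_static_equals_first_frame(self):
        atoms = [("A", i + 1, "GLY", "CA") for i in range(4)]
        base = np.array([[0, 0, 0], [3, 1, 0], [6, 0, 2], [9, 1, 1]], float)
        avg, minimised = average_structure(make_ens(atoms, [base] * 4))
        assert np.allclose(avg, base)
        assert minimised is False

    def test_two_frame_midpoint(self):
        atoms = [("A", i + 1, "GLY", "CA") for i in range(4)] + [("A", 5, "GLY", "CA")]
        base = np.array([[0, 0, 0], [3, 1, 0], [6, 0, 2], [9, 1, 1], [20, 0, 0]], float)
        up, down = base.copy(), base.copy()
        up[4, 2] += 1.0
        down[4, 2] -= 1.0
        avg, _ = average_structure(make_ens(atoms, [up, down]),
                                   fit_selection=AtomSelection.parse("A:1-4:CA"))
        assert np.allclose(avg[4], base[4], atol=1e-9)


# ---------------------------------------------------------------------------
# Selections / residue numbering
# ---------------------------------------------------------------------------


class TestSelections:
    def test_parse_forms(self):
        sel = AtomSelection.parse("A:70-125:CA")
        assert (sel.chain, sel.res_start, sel.res_stop, sel.atom_names) == ("A", 70, 125, ("CA",))
        sel = AtomSelection.parse("*:*:N+O")
        assert sel.chain is None and sel.atom_names == ("N", "O")

    def test_empty_selection_rejected(self):
        atoms = [("A", 1, "GLY", "CA")]
        ens = make_ens(atoms, [[[0, 0, 0]]])
        with pytest.raises(SelectionError, match="no atoms"):
            AtomSelection.parse("B:*:CA").resolve(ens)

    def test_residue_map_offset(self):
        rmap = ResidueMap()
        assert rmap.to_hrpe65(98) == 375 and rmap.to_hrpe65(102) == 379
        assert rmap.to_model(375) == 98


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def _donor_acceptor_ens(dist, angle_deg, with_h=True):
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    acceptor = place_acceptor(donor, hydrogen, dist, angle_deg)
    atoms = [("A", 1, "GLY", "N")]
    coords = [donor]
    if with_h:
        atoms.append(("A", 1, "GLY", "H"))
        coords.append(hydrogen)
    atoms.append(("A", 2, "GLY", "O"))
    coords.append(acceptor)
    return make_ens(atoms, [coords])


class TestDetectHbonds:
    @pytest.mark.parametrize("dist,angle,expected", [
        (2.9, 170.0, 1),   # well inside defaults
        (4.0, 170.0, 0),   # distance rejection
        (3.2, 100.0, 0),   # angle rejection below 135 deg
        (3.5, 135.0, 1),   # boundary accepted under >= / <= conventions
    ])
    def test_geometric_criteria(self, dist, angle, expected):
        ens = _donor_acceptor_ens(dist, angle)
        assert len(detect_hbonds(ens, 0)) == expected

    def test_heavy_atom_fallback_without_hydrogens(self):
        near = _donor_acceptor_ens(3.2, 170.0, with_h=False)
        assert len(detect_hbonds(near, 0)) > 0
        far = _donor_acceptor_ens(3.45, 170.0, with_h=False)
        assert len(detect_hbonds(far, 0)) == 0  # fallback cutoff is 3.3 Å
        with pytest.raises(ValueError, match="no hydrogens"):
            detect_hbonds(near, 0, HBondCriteria(allow_heavy_fallback=False))

    def test_intra_residue_pairs_excluded(self):
        atoms = [("A", 1, "SER", "N"), ("A", 1, "SER", "H"), ("A", 1, "SER", "OG")]
        coords = [[0, 0, 0], [1, 0, 0], [2.9, 0.3, 0]]
        assert detect_hbonds(make_ens(atoms, [coords]), 0) == []


def _pair_trajectory(n_bonded, n_total):
    """Two residues; the acceptor sits in bonded geometry for n_bonded frames."""
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    near = place_acceptor(donor, hydrogen, 2.9, 170.0)
    far = donor + np.array([6.0, 0.0, 0.0])
    atoms = [("A", 1, "GLY", "N"), ("A", 1, "GLY", "H"), ("A", 2, "GLY", "O")]
    frames = [[donor, hydrogen, near if f < n_bonded else far] for f in range(n_total)]
    return make_ens(atoms, frames)


class TestHbondOccupancy:
    def test_constructed_counts(self):
        rec = hbond_occupancy(_pair_trajectory(80, 100), (("A", 1), ("A", 2)))
        assert rec.occupancy == pytest.approx(0.80)
        assert rec.n_frames == 100
        rec = hbond_occupancy(_pair_trajectory(0, 50), (("A", 1), ("A", 2)))
        assert rec.occupancy == 0.0

    def test_frame_order_and_self_concatenation_invariance(self):
        ens = _pair_trajectory(7, 20)
        rec = hbond_occupancy(ens, (("A", 1), ("A", 2)))
        shuffled = dataclasses.replace(
            ens, coords=ens.coords[np.random.default_rng(0).permutation(20)])
        assert hbond_occupancy(shuffled, (("A", 1), ("A", 2))).occupancy == rec.occupancy
        doubled = ens.concat(ens)
        assert hbond_occupancy(doubled, (("A", 1), ("A", 2))).occupancy == rec.occupancy

    def test_bidentate_contact_counts_once_per_frame(self):
        # two simultaneous atom pairs in every frame; occupancy still 1.0
        donor = np.array([0.0, 0.0, 0.0])
        hydrogen = np.array([1.0, 0.0, 0.0])
        a1 = place_acceptor(donor, hydrogen, 2.9, 170.0)
        a2 = place_acceptor(donor, hydrogen, 3.0, 160.0)
        atoms = [("A", 1, "ASN", "ND2"), ("A", 1, "ASN", "HD21"),
                 ("A", 2, "GLU", "OE1"), ("A", 2, "GLU", "OE2")]
        ens = make_ens(atoms, [[donor, hydrogen, a1, a2]] * 3)
        rec = hbond_occupancy(ens, (("A", 1), ("A", 2)))
        assert rec.occupancy == 1.0
        assert len(rec.atom_pairs) == 2

    def test_unknown_residue_is_error(self):
        with pytest.raises(SelectionError, match="not found"):
            hbond_occupancy(_pair_trajectory(1, 2), (("A", 1), ("A", 99)))


class TestWaterBridge:
    def _bridge_ens(self, water_positions):
        atoms = [("A", 1, "SER", "OG"), ("B", 2, "GLU", "OE1")]
        coords = [[0.0, 0, 0], [5.0, 0, 0]]
        for i, w in enumerate(water_positions):
            atoms.append(("W", 10 + i, "HOH", "O"))
            coords.append(w)
        return make_ens(atoms, [coords])

    def test_single_bridging_water(self):
        ens = self._bridge_ens([[2.5, 1.0, 0.0]])  # ~2.7 Å from both partners
        rec = water_bridge_occupancy(ens, (("A", 1), ("B", 2)))
        assert rec.occupancy == 1.0 and rec.contact_class == "water_mediated"

    def test_water_near_only_one_partner(self):
        ens = self._bridge_ens([[0.0, 2.8, 0.0]])
        assert water_bridge_occupancy(ens, (("A", 1), ("B", 2))).occupancy == 0.0

    def test_two_waters_each_near_one_partner_not_bridged(self):
        ens = self._bridge_ens([[0.0, 2.8, 0.0], [5.0, 2.8, 0.0]])
        assert water_bridge_occupancy(ens, (("A", 1), ("B", 2))).occupancy == 0.0

    def test_no_waters_warns_zero(self):
        ens = self._bridge_ens([])
        assert water_bridge_occupancy(ens, (("A", 1), ("B", 2))).occupancy == 0.0


class TestContactOccupancy:
    def _ens(self, dist, n=1):
        atoms = [("A", 1, "VAL", "CG1"), ("B", 1, "VAL", "CG1")]
        return make_ens(atoms, [[[0, 0, 0], [dist, 0, 0]]] * n)

    def test_fixed_distances(self):
        assert contact_occupancy(self._ens(4.0), (("A", 1), ("B", 1))) == 1.0
        assert contact_occupancy(self._ens(6.0), (("A", 1), ("B", 1))) == 0.0

    def test_constructed_half_occupancy(self):
        atoms = [("A", 1, "VAL", "CG1"), ("B", 1, "VAL", "CG1")]
        frames = [[[0, 0, 0], [4.0 if f < 50 else 6.0, 0, 0]] for f in range(100)]
        assert contact_occupancy(make_ens(atoms, frames), (("A", 1), ("B", 1))) == 0.5


# ---------------------------------------------------------------------------
# Alert rules
# ---------------------------------------------------------------------------


class TestInteractionAlert:
    def test_native_set_thresholds(self, published):
        natives = native_interactions(published["wt_hbonds"])
        keys = {frozenset({("A", 303), ("A", 401)}), frozenset({("A", 303), ("A", 398)})}
        assert keys <= set(natives)
        # water-mediated transient contacts never become native
        assert frozenset({("A", 373), ("A", 322)}) not in natives

    @pytest.mark.parametrize("variant,resid,expected", [
        ("K303N", 303, True),    # lost charge-assisted bond to D398
        ("T400S", 400, False),   # all WT interactions efficiently maintained
        ("T390I", 390, True),    # K332B replacement below 50%
        ("D375N", 375, False),   # A377/D378 bonds kept at comparable stability
        ("V407A", 407, False),   # hydrophobic-only environment, nothing to lose
    ])
    def test_reference_judgments(self, published, variant, resid, expected):
        natives = native_interactions(published["wt_hbonds"])
        res = interaction_alert(natives, published["mutant_hbonds"][variant], ("A", resid))
        assert res.alert is expected

    def test_maintenance_rule_boundaries(self, published):
        natives = native_interactions(published["wt_hbonds"])
        # exactly at max(floor, wt - drop): D375N 0.55 -> 0.52 is maintained
        res = interaction_alert(natives, published["mutant_hbonds"]["D375N"], ("A", 375))
        assert res.alert is False and len(res.maintained) == 2

    def test_disrupted_pairs_report_both_occupancies(self, published):
        natives = native_interactions(published["wt_hbonds"])
        res = interaction_alert(natives, published["mutant_hbonds"]["K303N"], ("A", 303))
        assert len(res.disrupted) == 1
        entry = res.disrupted[0]
        assert entry["wt_occupancy"] == pytest.approx(0.55)
        assert entry["mut_occupancy"] == 0.0


def _metrics(rmsd_mean, rmsf_values, resids=None):
    resids = resids if resids is not None else range(1, len(rmsf_values) + 1)
    return StructuralMetrics(
        rmsd_series=np.full(10, rmsd_mean),
        second_half_mean_rmsd=rmsd_mean,
        rmsf=pd.Series(rmsf_values, index=list(resids)),
    )


class TestStructuralAlert:
    def test_rmsd_criterion(self):
        wt = _metrics(1.0, [0.6] * 10)
        mut = _metrics(1.6, [0.7] * 10)
        res = structural_alert(mut, wt)
        assert res.alert and res.rmsd_criterion and not res.rmsf_criterion

    def test_rmsf_peak_criterion(self):
        wt = _metrics(1.0, [0.6] * 10)
        vals = [0.7] * 10
        vals[4:7] = [2.9, 3.0, 2.9]
        mut = _metrics(1.0, vals)
        res = structural_alert(mut, wt)
        assert res.alert and res.rmsf_criterion and not res.rmsd_criterion
        assert res.evidence["rmsf_peak_residues"] == [5, 6, 7]

    def test_short_or_elevated_wt_runs_do_not_fire(self):
        wt_vals = [0.6] * 10
        vals = [0.7] * 10
        vals[4:6] = [3.0, 3.0]  # run of 2 < window of 3
        assert not structural_alert(_metrics(1.0, vals), _metrics(1.0, wt_vals)).alert
        vals[4:7] = [3.0, 3.0, 3.0]
        wt_vals[4:7] = [1.5, 1.5, 1.5]  # WT itself mobile there
        assert not structural_alert(_metrics(1.0, vals), _metrics(1.0, wt_vals)).alert

    def test_identical_metrics_no_alert(self):
        wt = _metrics(1.0, [0.6] * 10)
        assert structural_alert(wt, wt).alert is False

    def test_mismatched_residue_coverage_rejected(self):
        wt = _metrics(1.0, [0.6] * 10)
        mut = _metrics(1.0, [0.6] * 9)
        with pytest.raises(SelectionError, match="different residues"):
            structural_alert(mut, wt)
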