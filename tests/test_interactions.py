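"""Hydrogen-bond, π-contact and van der Waals detectors vs brute force."""

import numpy as np
import pytest

from porescan import (
    ContactEpoch,
    DegenerateGeometryError,
    HBondCriterion,
    PlantedHBond,
    ScenarioSpec,
    Topology,
    assign_roles,
    detect_hbonds,
    generate_trajectory,
    hbond_occupancy,
    is_abolished,
    panel_total,
    pi_contact_series,
    resolve_selection,
    total_hb_number,
    vdw_contact_series,
)
from porescan.interactions import _atom_roles
from porescan.trajio import Trajectory

from conftest import random_rotation


def _donor_acceptor_topology(with_h=True):
    """Residue 1: backbone N donor (+H); residue 2: carbonyl O acceptor."""
    names = ["N", "H", "O"] if with_h else ["N", "O"]
    elements = [n[0] for n in names]
    resids = [1, 1, 2] if with_h else [1, 2]
    return Topology(
        names=np.array(names),
        elements=np.array(elements),
        resnames=np.array(["GLY"] * len(names)),
        resids=np.array(resids),
        chains=np.array(["A"] * len(names)),
    )


def _dha_coords(da_dist, angle_deg):
    """Donor at origin, H on +x at 1.0 Å, acceptor placed so the D-H...A
    angle equals ``angle_deg`` and |D-A| = ``da_dist``."""
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    # find acceptor: solve on the x-y plane
    ang = np.deg2rad(angle_deg)
    # direction of H->A makes (180 - angle at H ... ) use law of cosines
    # place A at distance r from H such that |D-A| = da_dist with the
    # H-angle = angle_deg between H->D and H->A
    hd = d - h
    # unit vectors: H->D is -x; rotate by angle to get H->A direction
    c, s = np.cos(ang), np.sin(ang)
    u = np.array([-c, s, 0.0])  # angle between u and H->D(-x) is angle_deg
    # choose r solving |h + r u - d| = da_dist
    # |h + r u|^2 = 1 + r^2 + 2 r (h . u) with h = +x -> h.u = -c
    r = np.roots([1.0, -2 * c, 1 - da_dist**2])
    r = float(max(r))
    a = h + r * u
    assert np.isclose(np.linalg.norm(a - d), da_dist)
    return np.array([d, h, a])


class TestDetectHbonds:
    def test_inside_both_cutoffs_is_satisfied(self):
        top = _donor_acceptor_topology()
        coords = _dha_coords(2.9, 160.0)
        pairs = detect_hbonds(top, coords, np.array([0]), np.array([2]),
                              HBondCriterion(hydrogen_mode="explicit"))
        assert pairs == [(0, 2)]

    def test_beyond_distance_cutoff_is_excluded(self):
        top = _donor_acceptor_topology()
        coords = _dha_coords(3.6, 160.0)
        pairs = detect_hbonds(top, coords, np.array([0]), np.array([2]),
                              HBondCriterion(da_cutoff=3.5,
                                             hydrogen_mode="explicit"))
        assert pairs == []

    def test_bad_angle_is_excluded_in_explicit_mode(self):
        top = _donor_acceptor_topology()
        coords = _dha_coords(2.9, 100.0)
        crit = HBondCriterion(dha_min_angle=135.0, hydrogen_mode="explicit")
        assert detect_hbonds(top, coords, np.array([0]), np.array([2]),
                             crit) == []
        # inferred mode is distance-only, so the same geometry passes
        crit2 = HBondCriterion(dha_min_angle=135.0, hydrogen_mode="inferred")
        assert detect_hbonds(top, coords, np.array([0]), np.array([2]),
                             crit2) == [(0, 2)]

    def test_randomized_frames_match_brute_force(self, rng):
        """Detector output equals exhaustive evaluation on random frames."""
        n_res = 25
        names, elements, resids = [], [], []
        for r in range(n_res):
            names += ["N", "H", "O"]
            elements += ["N", "H", "O"]
            resids += [r, r, r]
        top = Topology(
            names=np.array(names), elements=np.array(elements),
            resnames=np.array(["GLY"] * len(names)),
            resids=np.array(resids), chains=np.array(["A"] * len(names)),
        )
        donors = np.flatnonzero(top.names == "N")
        acceptors = np.flatnonzero(top.names == "O")
        crit = HBondCriterion(hydrogen_mode="explicit")
        for _ in range(100):
            coords = rng.uniform(0, 12.0, size=(len(names), 3))
            # keep each H within bonding distance of its donor
            for d in donors:
                coords[d + 1] = coords[d] + rng.normal(0, 0.4, 3)
                coords[d + 1] = coords[d] + (
                    (coords[d + 1] - coords[d])
                    / np.linalg.norm(coords[d + 1] - coords[d])
                )
            got = set(detect_hbonds(top, coords, donors, acceptors, crit))
            expected = set()
            for d in donors:
                h = coords[d + 1]
                for a in acceptors:
                    if top.resids[a] == top.resids[d]:
                        continue
                    if np.linalg.norm(coords[d] - coords[a]) > 3.5:
                        continue
                    v1 = coords[d] - h
                    v2 = coords[a] - h
                    cosang = v1 @ v2 / (np.linalg.norm(v1)
                                        * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang >= 135.0:
                        expected.add((int(d), int(a)))
            assert got == expected

    def test_rigid_motion_leaves_detection_unchanged(self, rng):
        top = _donor_acceptor_topology()
        coords = _dha_coords(2.9, 160.0)
        rot = random_rotation(rng)
        moved = coords @ rot.T + rng.normal(size=3) * 10
        crit = HBondCriterion(hydrogen_mode="explicit")
        assert (detect_hbonds(top, coords, np.array([0]), np.array([2]), crit)
                == detect_hbonds(top, moved, np.array([0]), np.array([2]),
                                 crit))


class TestOccupancy:
    def test_always_satisfied_pair_has_occupancy_one(self):
        top = _donor_acceptor_topology(with_h=False)
        coords = np.array([[0.0, 0, 0], [2.9, 0, 0]])
        traj = Trajectory(top, np.stack([coords] * 5), np.arange(5.0))
        occ = hbond_occupancy(traj, np.array([0]), np.array([1]))
        assert len(occ) == 1 and occ[0].occupancy == 1.0

    def test_never_satisfied_pair_is_omitted(self):
        top = _donor_acceptor_topology(with_h=False)
        coords = np.array([[0.0, 0, 0], [9.0, 0, 0]])
        traj = Trajectory(top, np.stack([coords] * 5), np.arange(5.0))
        assert hbond_occupancy(traj, np.array([0]), np.array([1])) == []

    def test_planted_occupancy_recovered(self):
        """A planted 0.75 occupancy is recovered within binomial noise."""
        hb = PlantedHBond(196, "NH2", 2, "OP1", 0.75)
        spec = ScenarioSpec(kind="entrapment", n_frames=2000,
                            frame_interval_ns=1.0, noise_sigma=0.5, seed=17,
                            planted_hbonds=(hb,))
        traj, truth = generate_trajectory(spec)
        don = resolve_selection(traj.topology, "resid 196 and name NH2")
        acc = resolve_selection(traj.topology, "resid 2 and name OP1")
        occ = hbond_occupancy(traj, don, acc)
        pair = {(o.donor, o.acceptor): o.occupancy for o in occ}
        got = pair[(int(don[0]), int(acc[0]))]
        assert abs(got - 0.75) <= 0.05
        realized = truth.planted_occupancies["196:NH2-2:OP1"]["realized"]
        assert got == pytest.approx(realized, abs=1e-12)


class TestTotals:
    @staticmethod
    def _planted_panel(sigma=0.0, seed=23, n_frames=400):
        plants = (
            PlantedHBond(196, "NH1", 2, "OP1", 0.9),
            PlantedHBond(196, "NH2", 2, "OP2", 0.8),
            PlantedHBond(196, "NE", 2, "OP1", 0.7),
        )
        spec = ScenarioSpec(kind="entrapment", n_frames=n_frames,
                            frame_interval_ns=1.0, noise_sigma=sigma,
                            seed=seed, planted_hbonds=plants)
        traj, truth = generate_trajectory(spec)
        don = resolve_selection(traj.topology, "resid 196 and name NH1 NH2 NE")
        acc = resolve_selection(traj.topology, "resid 2 and name OP1 OP2")
        occ = hbond_occupancy(traj, don, acc)
        return traj, truth, occ

    def test_single_pair_total_equals_its_occupancy(self):
        top = _donor_acceptor_topology(with_h=False)
        # make residue 2 a nucleotide backbone acceptor
        top = Topology(
            names=np.array(["NZ", "OP1"]),
            elements=np.array(["N", "O"]),
            resnames=np.array(["LYS", "DT"]),
            resids=np.array([216, 2]),
            chains=np.array(["A", "D"]),
        )
        coords = np.array([[0.0, 0, 0], [2.9, 0, 0]])
        traj = Trajectory(top, np.stack([coords] * 10), np.arange(10.0))
        occ = hbond_occupancy(traj, np.array([0]), np.array([1]))
        totals = total_hb_number(top, occ)
        assert len(totals) == 1
        t = totals[0]
        assert (t.residue, t.nucleotide, t.moiety) == (216, 2, "backbone")
        assert t.total_hb == pytest.approx(occ[0].occupancy)

    def test_group_total_is_sum_of_member_occupancies(self):
        """Pairs planted at {0.9, 0.8, 0.7} in one residue-nucleotide group
        sum to ~2.4, and the total equals the realized sum exactly."""
        traj, truth, occ = self._planted_panel()
        totals = total_hb_number(traj.topology, occ)
        grp = [t for t in totals
               if (t.residue, t.nucleotide, t.moiety) == (196, 2, "backbone")]
        assert len(grp) == 1
        realized = sum(v["realized"]
                       for v in truth.planted_occupancies.values())
        assert grp[0].total_hb == pytest.approx(realized, abs=1e-12)
        assert grp[0].total_hb == pytest.approx(2.4, abs=0.15)
        assert grp[0].n_pairs == 3

    def test_additivity_under_group_splitting(self):
        traj, _, occ = self._planted_panel(seed=29)
        totals = total_hb_number(traj.topology, occ)
        whole = panel_total(totals, residues={196})
        parts = sum(
            panel_total(total_hb_number(traj.topology, [o]), residues={196})
            for o in occ
        )
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_unmapped_pair_is_an_error_naming_atoms(self):
        top = _donor_acceptor_topology(with_h=False)  # both protein side
        from porescan.interactions import HBondPairOccupancy
        from porescan import PorescanError

        with pytest.raises(PorescanError, match="GLY"):
            total_hb_number(top, [HBondPairOccupancy(0, 1, 0.5)])


def _ring_topology():
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2", "NZ"]
    return Topology(
        names=np.array(names),
        elements=np.array([n[0] for n in names]),
        resnames=np.array(["PHE"] * 6 + ["LYS"]),
        resids=np.array([10] * 6 + [20]),
        chains=np.array(["A"] * 7),
    )


def _ring_coords(radius=1.4):
    ang = np.deg2rad(np.arange(6) * 60.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(6)])


class TestPiContacts:
    def test_on_axis_cation_is_satisfied(self):
        top = _ring_topology()
        coords = np.vstack([_ring_coords(), [0.0, 0.0, 4.0]])
        traj = Trajectory(top, coords[None], np.array([0.0]))
        pc = pi_contact_series(traj, "cation_pi", 6, np.arange(6))
        assert pc.satisfied_fraction == 1.0
        assert pc.distances.values[0] == pytest.approx(4.0)

    def test_in_plane_cation_is_rejected_by_angle(self):
        top = _ring_topology()
        coords = np.vstack([_ring_coords(), [4.0, 0.0, 0.0]])
        traj = Trajectory(top, coords[None], np.array([0.0]))
        pc = pi_contact_series(traj, "cation_pi", 6, np.arange(6))
        assert pc.satisfied_fraction == 0.0

    def test_collinear_ring_has_no_normal(self):
        top = _ring_topology()
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        coords = np.vstack([line, [0.0, 0.0, 4.0]])
        traj = Trajectory(top, coords[None], np.array([0.0]))
        with pytest.raises(DegenerateGeometryError):
            pi_contact_series(traj, "cation_pi", 6, np.arange(6))

    def test_wrong_atom_identity_rejected(self):
        top = _ring_topology()
        coords = np.vstack([_ring_coords(), [0.0, 0.0, 4.0]])
        traj = Trajectory(top, coords[None], np.array([0.0]))
        with pytest.raises(ValueError, match="CZ or Lys NZ"):
            pi_contact_series(traj, "cation_pi", 0, np.arange(1, 6))

    def test_random_placements_match_brute_force(self, rng):
        """Satisfied set over random placements equals an exhaustive
        geometric evaluation."""
        top = _ring_topology()
        ring = _ring_coords()
        n = 200
        placements = rng.uniform(-7, 7, size=(n, 3))
        coords = np.stack([np.vstack([ring, p]) for p in placements])
        traj = Trajectory(top, coords, np.arange(float(n)))
        pc = pi_contact_series(traj, "cation_pi", 6, np.arange(6))
        centroid = ring.mean(axis=0)
        for f, p in enumerate(placements):
            v = p - centroid
            dist = np.linalg.norm(v)
            cosang = abs(v[2]) / dist  # ring normal is z by construction
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            expected = (dist <= 6.0) and (ang <= 45.0)
            assert pc.satisfied[f] == expected


class TestVdw:
    def test_disjoint_groups_count_zero_and_abolished(self, rng):
        top = Topology(
            names=np.array(["C"] * 6),
            elements=np.array(["C"] * 6),
            resnames=np.array(["ALA"] * 3 + ["DT"] * 3),
            resids=np.array([1, 1, 1, 2, 2, 2]),
            chains=np.array(["A"] * 3 + ["D"] * 3),
        )
        coords = np.vstack([rng.normal(0, 1, (3, 3)),
                            rng.normal(0, 1, (3, 3)) + 25.0])
        traj = Trajectory(top, np.stack([coords] * 4), np.arange(4.0))
        s = vdw_contact_series(traj, np.arange(3), np.arange(3, 6))
        assert np.all(s.values == 0)
        assert is_abolished(s, (0.0, 3.0))

    def test_single_pair_at_four_angstrom(self):
        top = Topology(
            names=np.array(["C", "C"]),
            elements=np.array(["C", "C"]),
            resnames=np.array(["ALA", "DT"]),
            resids=np.array([1, 2]),
            chains=np.array(["A", "D"]),
        )
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        traj = Trajectory(top, np.stack([coords] * 3), np.arange(3.0))
        s = vdw_contact_series(traj, np.array([0]), np.array([1]))
        assert np.all(s.values == 1)
        assert not is_abolished(s, (0.0, 2.0))

    def test_random_clouds_match_brute_force(self, rng):
        n = 10
        top = Topology(
            names=np.array(["C"] * (2 * n)),
            elements=np.array(["C"] * (2 * n)),
            resnames=np.array(["ALA"] * n + ["DT"] * n),
            resids=np.array([1] * n + [2] * n),
            chains=np.array(["A"] * n + ["D"] * n),
        )
        coords = rng.uniform(0, 10, size=(20, 2 * n, 3))
        traj = Trajectory(top, coords, np.arange(20.0))
        s = vdw_contact_series(traj, np.arange(n), np.arange(n, 2 * n))
        for f in range(20):
            brute = sum(
                np.linalg.norm(coords[f, i] - coords[f, j]) <= 4.5
                for i in range(n) for j in range(n, 2 * n)
            )
            assert s.values[f] == brute


class TestRoleTemplates:
    @pytest.mark.parametrize("resname,name,don,acc", [
        ("ARG", "NH1", True, False),
        ("ASP", "OD1", False, True),
        ("TYR", "OH", True, True),
        ("DT", "N3", True, False),
        ("DT", "O4", False, True),
        ("DT", "OP1", False, True),
        ("T64", "5TN3", True, False),
        ("T64", "3TO2", False, True),
        ("T64", "OP2", False, True),
    ])
    def test_role_assignment(self, resname, name, don, acc):
        top = Topology(
            names=np.array([name]),
            elements=np.array([name.lstrip("53T")[0] if name[0] in "53"
                               else name[0]]),
            resnames=np.array([resname]),
            resids=np.array([1]),
            chains=np.array(["A"]),
        )
        assert _atom_roles(top, 0) == (don, acc)

    def test_atoms_without_template_warn_and_drop(self):
        with pytest.warns(UserWarning, match="no donor/acceptor template"):
            t2 = Topology(
                names=np.array(["NX"]),
                elements=np.array(["N"]),
                resnames=np.array(["ALA"]),
                resids=np.array([1]),
                chains=np.array(["A"]),
            )
            don, acc = assign_roles(t2, np.array([0]))
        assert don.size == 0 and acc.size == 0
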