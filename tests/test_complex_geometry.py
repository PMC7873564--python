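"""Interface contacts, constraints, superposition, tiling and calibration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fcmurkit import complex_geometry as cg
from fcmurkit import synthetic_data as sd


def ca_structure(chain, coords, res_start=1):
    return sd._ca_structure(chain, np.asarray(coords, float), res_start)


def random_structure(rng, chain, n_res, scale=15.0):
    return ca_structure(chain, rng.uniform(0, scale, size=(n_res, 3)))


def brute_force_residue_pairs(a, b, cutoff):
    pairs = set()
    for i in range(len(a)):
        for j in range(len(b)):
            d = np.linalg.norm(a.coords[i] - b.coords[j])
            if d <= cutoff:
                pairs.add((
                    (str(a.chain_id[i]), int(a.res_id[i])),
                    (str(b.chain_id[j]), int(b.res_id[j])),
                ))
    return pairs


class TestResidueContacts:
    def test_far_apart_no_contacts(self):
        a = ca_structure("A", [[0, 0, 0], [1, 0, 0]])
        b = ca_structure("B", [[100, 0, 0], [101, 0, 0]])
        assert cg.residue_contacts(a, b, 5.0).n_contacts == 0

    def test_constructed_single_pair(self):
        a = ca_structure("A", [[0, 0, 0], [0, 0, 20]])
        b = ca_structure("B", [[3.9, 0, 0], [30, 30, 30]])
        rep = cg.residue_contacts(a, b, 4.5)
        assert set(rep.pairs) == {(("A", 1), ("B", 1))}
        assert rep.pairs[(("A", 1), ("B", 1))] == pytest.approx(3.9)

    def test_matches_brute_force_oracle_and_symmetry(self):
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            a = random_structure(rng, "A", 20)
            b = random_structure(rng, "B", 20)
            rep = cg.residue_contacts(a, b, 5.0)
            assert set(rep.pairs) == brute_force_residue_pairs(a, b, 5.0)
            flipped = cg.residue_contacts(b, a, 5.0)
            assert {(x, y) for y, x in flipped.pairs} == set(rep.pairs)

    def test_empty_selection_rejected(self):
        a = ca_structure("A", [[0, 0, 0]])
        with pytest.raises(ValueError):
            cg.residue_contacts(a, a.subset(np.zeros(1, bool)), 5.0)


class TestDomainFraction:
    def make_report(self, n_cmu4, n_cmu3):
        pairs = {}
        for i in range(n_cmu4):
            pairs[(("R", i + 1), ("A", 20 + i))] = 4.0
        for i in range(n_cmu3):
            pairs[(("R", 50 + i), ("A", 1 + i))] = 4.0
        return cg.InterfaceReport(pairs=pairs, cutoff=5.0)

    def test_all_in_one_region(self):
        rep = self.make_report(4, 0)
        frac = cg.domain_contact_fraction(rep, {"Cmu4": [("A", 13, 30)]})
        assert frac["Cmu4"] == 1.0

    def test_exact_three_quarters_fails_strict_filter(self):
        rep = self.make_report(3, 1)
        frac = cg.domain_contact_fraction(
            rep, {"Cmu4": [("A", 13, 30)], "Cmu3": [("A", 1, 12)]}
        )
        assert frac["Cmu4"] == pytest.approx(0.75)
        assert not frac["Cmu4"] > 0.75  # boundary: "most contacts" is strict

    def test_fractions_sum_to_one_with_other(self):
        rep = self.make_report(3, 2)
        frac = cg.domain_contact_fraction(rep, {"Cmu4": [("A", 13, 30)]})
        assert sum(frac.values()) == pytest.approx(1.0)
        assert frac["other"] == pytest.approx(2 / 5)


class TestCheckConstraints:
    def test_good_pose_passes(self, good_pose):
        rep = cg.check_constraints(
            good_pose.complex(), ["R"], list(good_pose.ligand_chains),
            good_pose.constraints,
        )
        assert rep.passed
        # PASS implies every required residue shows up in the contact report
        for ref in good_pose.constraints.required_receptor:
            assert rep.interface.involves(ref)
        for ref in good_pose.constraints.required_ligand:
            assert rep.interface.involves(ref)

    def test_translated_pose_fails_all_required(self, good_pose):
        comp = good_pose.complex()
        mask = np.isin(comp.chain_id, ["R", "S"])
        comp.coords[mask] += np.array([0.0, 0.0, 50.0])
        rep = cg.check_constraints(
            comp, ["R"], list(good_pose.ligand_chains), good_pose.constraints
        )
        assert not rep.passed
        required = [it for it in rep.items if it.name.startswith("required")]
        assert required and all(not it.passed for it in required)

    def test_decoy_excluded_chain_contact_fails(self, good_pose):
        # drop a decoy chain right between receptor and ligand
        comp = good_pose.complex()
        r_centroid = comp.subset(["R"]).centroid()
        lig = comp.subset(list(good_pose.ligand_chains))
        # place decoy atoms along the gap under the receptor binding face
        decoy = ca_structure("X", r_centroid[None, :] + [[0, 0, -4.0]])
        full = cg.Structure.concat([comp, decoy])
        constraints = cg.DockConstraints(
            required_receptor=good_pose.constraints.required_receptor,
            required_ligand=good_pose.constraints.required_ligand,
            forbidden_receptor=good_pose.constraints.forbidden_receptor,
            excluded_chains=("X",),
            domain_regions=good_pose.constraints.domain_regions,
            dominant_region="Cmu4",
            glyco_site=good_pose.constraints.glyco_site,
        )
        rep = cg.check_constraints(
            full, ["R"], list(good_pose.ligand_chains), constraints
        )
        assert not rep.item("excluded_chain:X").passed

    def test_unresolvable_residue_reported(self, good_pose):
        constraints = cg.DockConstraints(
            required_receptor=(("R", 999),),
            required_ligand=good_pose.constraints.required_ligand,
            forbidden_receptor=(),
        )
        with pytest.raises(KeyError, match="R:999"):
            cg.check_constraints(
                good_pose.complex(), ["R"], list(good_pose.ligand_chains),
                constraints,
            )

    def test_rigid_motion_invariance(self, good_pose):
        comp = good_pose.complex()
        R = Rotation.random(rng=np.random.default_rng(4)).as_matrix()
        moved = comp.transformed(R, np.array([12.0, -30.0, 7.0]))
        rep0 = cg.check_constraints(
            comp, ["R"], list(good_pose.ligand_chains), good_pose.constraints
        )
        rep1 = cg.check_constraints(
            moved, ["R"], list(good_pose.ligand_chains), good_pose.constraints
        )
        assert rep0.passed == rep1.passed
        assert set(rep0.interface.pairs) == set(rep1.interface.pairs)


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        R, t, rmsd = cg.kabsch_superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_random_rotation(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(25, 3))
        for seed in range(5):
            R_true = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            t_true = rng.normal(size=3) * 10
            target = pts @ R_true.T + t_true
            R, t, rmsd = cg.kabsch_superpose(pts, target)
            assert np.allclose(R, R_true, atol=1e-6)
            assert rmsd < 1e-6

    def test_reflection_not_allowed(self, rng):
        pts = rng.normal(size=(12, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        R, _, rmsd = cg.kabsch_superpose(pts, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_optimal_vs_random_rotations(self, rng):
        mobile = rng.normal(size=(15, 3))
        target = rng.normal(size=(15, 3))
        _, _, rmsd = cg.kabsch_superpose(mobile, target)
        m0 = mobile - mobile.mean(0)
        t0 = target - target.mean(0)
        for seed in range(100):
            R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            trial = np.sqrt(((m0 @ R.T - t0) ** 2).sum(1).mean())
            assert rmsd <= trial + 1e-12

    def test_agrees_with_scipy_align_vectors(self, rng):
        mobile = rng.normal(size=(20, 3))
        target = rng.normal(size=(20, 3))
        R, _, rmsd = cg.kabsch_superpose(mobile, target)
        rot, rssd = Rotation.align_vectors(
            target - target.mean(0), mobile - mobile.mean(0)
        )
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(mobile)), rel=1e-6)

    def test_collinear_rejected(self):
        line = np.arange(5)[:, None] * np.array([1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            cg.kabsch_superpose(line, line)


class TestClashAndAccessibility:
    def test_superposed_copies_clash(self, rng):
        pts = rng.normal(size=(8, 3))
        assert cg.clash_check(pts, pts).clash

    def test_distant_domains_no_clash(self, rng):
        pts = rng.normal(size=(8, 3))
        res = cg.clash_check(pts, pts + 50.0)
        assert not res.clash and res.n_pairs == 0

    def test_single_close_pair_counted(self):
        a = np.array([[0.0, 0, 0], [10, 0, 0]])
        b = np.array([[2.0, 0, 0], [20, 0, 0]])
        res = cg.clash_check(a, b, min_dist=2.5)
        assert res.clash and res.n_pairs == 1
        assert res.min_distance == pytest.approx(2.0)

    def test_glycan_filter_far_and_near(self, good_pose):
        comp = good_pose.complex()
        with pytest.warns(UserWarning, match="side-chain"):
            assert cg.glycan_filter(comp, good_pose.constraints.glyco_site, ["R"])
        # drop a receptor atom inside the pseudo-glycan sphere
        site_xyz = comp.residue_atoms(good_pose.constraints.glyco_site)[0]
        intruder = ca_structure("R", site_xyz[None, :] + [[1.0, 0, 0]],
                                res_start=900)
        spiked = cg.Structure.concat([comp, intruder])
        with pytest.warns(UserWarning, match="side-chain"):
            assert not cg.glycan_filter(
                spiked, good_pose.constraints.glyco_site, ["R"]
            )

    def test_cterm_away_from_isolated_ligand_accessible(self):
        receptor = ca_structure("R", [[0, 0, 0], [0, 0, 3], [0, 0, 6]])
        ligand = ca_structure("A", [[0, 0, -20]])
        assert cg.cterm_accessibility(receptor, ligand)

    def test_cterm_buried_in_sandwich(self):
        # C-terminus pinned between two ligand walls within the clearance
        receptor = ca_structure("R", [[0, 0, 12], [0, 0, 6], [0, 0, 0]])
        walls = ca_structure("A", [[3.0, 0, 0], [-3.0, 0, 0]])
        assert not cg.cterm_accessibility(receptor, walls, threshold=8.0)

    def test_single_residue_far_from_everything_accessible(self):
        receptor = ca_structure("R", [[0, 0, 0]])
        ligand = ca_structure("A", [[100, 0, 0]])
        assert cg.cterm_accessibility(receptor, ligand)


class TestTiling:
    def test_good_pose_ten_accessible_sites(self, good_pose):
        ps = cg.tile_pentamer(
            good_pose.pentamer, list(good_pose.receptors),
            good_pose.subunit_chain_pairs,
        )
        assert ps.n == 10
        assert ps.clash_count == 0
        assert ps.accessible_count == 10

    def test_tiling_consistency_under_symmetry(self, good_pose):
        """Aligning each placement back onto its own subunit must reproduce
        the source placement to numerical precision on a C5 fixture."""
        ps = cg.tile_pentamer(
            good_pose.pentamer, list(good_pose.receptors),
            good_pose.subunit_chain_pairs,
        )
        ref_upper = ps.placements[0].receptor.coords
        for p in ps.placements[::2]:  # upper-chain placements, one per subunit
            back = (p.receptor.coords - p.translation) @ p.rotation
            rmsd = np.sqrt(((back - ref_upper) ** 2).sum(1).mean())
            assert rmsd < 1e-6

    def test_fused_subunits_flagged_clashing(self, good_pose):
        # overlap subunit 1 onto subunit 0: placements tiled there collide
        pent = good_pose.pentamer
        c0 = good_pose.subunit_chain_pairs[0]
        c1 = good_pose.subunit_chain_pairs[1]
        coords = pent.coords.copy()
        m1 = np.isin(pent.chain_id, list(c1))
        coords[m1] = pent.coords[np.isin(pent.chain_id, list(c0))]
        fused = cg.Structure(
            chain_id=pent.chain_id, res_id=pent.res_id, res_name=pent.res_name,
            atom_name=pent.atom_name, element=pent.element, coords=coords,
        )
        ps = cg.tile_pentamer(
            fused, list(good_pose.receptors), good_pose.subunit_chain_pairs
        )
        assert ps.clash_count > 0
        assert ps.accessible_count < 10

    def test_single_subunit_two_placements(self):
        fx = sd.gen_pentamer_complex(sd.PentamerParams(n_subunits=1))
        ps = cg.tile_pentamer(
            fx.pentamer, list(fx.receptors), fx.subunit_chain_pairs
        )
        assert ps.n == 2

    def test_residue_count_mismatch_rejected(self, good_pose):
        pent = good_pose.pentamer
        trimmed = pent.subset(~(
            (pent.chain_id == good_pose.subunit_chain_pairs[1][0])
            & (pent.res_id == 1)
        ))
        with pytest.raises(ValueError, match="does not match"):
            cg.tile_pentamer(
                trimmed, list(good_pose.receptors), good_pose.subunit_chain_pairs
            )


class TestAffinityCalibration:
    def test_two_points_exact_interpolation(self):
        cal = cg.fit_affinity_calibration([(780.0, 1e6), (1110.0, 1e9)])
        assert cal.predict(780.0) == pytest.approx(1e6, rel=1e-9)
        assert cal.predict(1110.0) == pytest.approx(1e9, rel=1e-9)

    def test_line_through_known_points(self):
        cal = cg.fit_affinity_calibration([(400.0, 1e4), (1200.0, 1e10)])
        assert cal.predict(800.0) == pytest.approx(1e7, rel=1e-9)

    def test_noisy_slope_recovery_within_three_se(self, rng):
        slope, intercept = 0.0075, 1.0
        scores = rng.uniform(400, 1200, size=40)
        log_ka = slope * scores + intercept + rng.normal(0, 0.3, size=40)
        cal = cg.AffinityCalibration().fit(scores, 10.0 ** log_ka)
        x = scores - scores.mean()
        resid = log_ka - cal.predict_log10_ka(scores)
        se = np.sqrt((resid**2).sum() / (len(scores) - 2) / (x**2).sum())
        assert abs(cal.slope_ - slope) < 3 * se

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            cg.fit_affinity_calibration([(500.0, 1e5), (500.0, 1e7)])

    def test_nonpositive_ka_rejected(self):
        with pytest.raises(ValueError):
            cg.fit_affinity_calibration([(500.0, 1e5), (600.0, -1.0)])


class TestPdbIO:
    def test_structure_roundtrip(self, tmp_path, good_pose):
        comp = good_pose.complex()
        path = tmp_path / "complex.pdb"
        comp.to_pdb(path)
        back = cg.Structure.from_pdb(path)
        assert len(back) == len(comp)
        assert set(back.chains) == set(comp.chains)
        assert np.allclose(back.coords, comp.coords, atol=2e-3)
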