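import numpy as np
import pytest
from scipy.spatial.distance import cdist

from soltemp.examples import cluster_strand_flags
from soltemp.interactions import (
    AnalysisConfig,
    beta_regions,
    binding_propensity,
    contact_map,
    hydrogen_bonds,
    residue_contact,
    rmsf,
    salt_bridges,
    sheet_associations,
)
from soltemp.io_model import Trajectory
from soltemp.secondary_structure import assign_ss, backbone_hbond_matrix
from soltemp.synthetic_traj import (
    AB42_SEQUENCE,
    build_peptide_topology,
    coil_coordinates,
    plant_hairpin,
)


def _pair_topology(dist):
    """Two 1-atom... actually two-residue toy with SC tips ``dist`` apart."""
    top = build_peptide_topology("DK")
    coords = coil_coordinates(top)
    # move residue 1 far away, then bring the SC tips to `dist`
    idx1 = top.residue_atoms(1)
    coords[idx1] += 100.0
    sc0 = top.residue_atoms(0)[top.atom_names[top.residue_atoms(0)] == "SC"][0]
    sc1 = idx1[top.atom_names[idx1] == "SC"][0]
    coords[sc1] = coords[sc0] + [dist, 0, 0]
    return top, coords, sc0, sc1


class TestResidueContact:
    @pytest.mark.parametrize("dist,expected", [(5.3, True), (5.5, False)])
    def test_cutoff_boundary(self, dist, expected):
        top, coords, _, _ = _pair_topology(dist)
        c = residue_contact(coords, top, [0], [1], cutoff=5.4)
        assert bool(c[0, 0]) is expected

    def test_matches_brute_force(self, small_ensemble):
        traj, _ = small_ensemble
        top = traj.topology
        lig = top.chain_residues("A")[:10]
        rec = top.chain_residues("R")[:10]
        frame = traj.xyz[0]
        got = residue_contact(frame, top, lig, rec, cutoff=5.4)
        for i, ra in enumerate(lig):
            ia = top.residue_atoms(int(ra))
            ia = ia[top.is_heavy[ia]]
            for j, rb in enumerate(rec):
                ib = top.residue_atoms(int(rb))
                ib = ib[top.is_heavy[ib]]
                assert got[i, j] == (cdist(frame[ia], frame[ib]).min()
                                     <= 5.4)


class TestContactMap:
    def test_single_frame_entries_binary(self, small_ensemble):
        traj, _ = small_ensemble
        sub = Trajectory(traj.topology, traj.xyz[:1])
        cmap = contact_map(sub, chain="A")
        off_diag = cmap.probabilities[~np.eye(42, dtype=bool)]
        assert set(np.unique(off_diag)).issubset({0.0, 1.0})

    def test_symmetric_probabilities(self, small_ensemble):
        traj, _ = small_ensemble
        sub = Trajectory(traj.topology, traj.xyz[:30])
        cmap = contact_map(sub, chain="A")
        assert np.allclose(cmap.probabilities, cmap.probabilities.T)
        assert cmap.probabilities.min() >= 0
        assert cmap.probabilities.max() <= 1

    def test_hairpin_contacts_follow_planting(self, small_ensemble):
        traj, truth = small_ensemble
        cmap = contact_map(traj, chain="A")
        hairpin_frames = truth.beta_labels[:, 16].mean()
        # paired strand residues (17<->35 in 0-based register) touch in
        # exactly the hairpin frames
        assert cmap.probabilities[17, 34] == pytest.approx(hairpin_frames,
                                                           abs=0.02)


class TestBindingPropensity:
    def test_unbound_only_is_zero(self):
        from soltemp.synthetic_traj import SynthConfig, generate_ensemble

        cfg = SynthConfig(n_frames=10, unbound_probability=1.0,
                          saltbridge_spec=[], seed=41)
        traj, _ = generate_ensemble(cfg)
        lp, lmean, rp, rmean = binding_propensity(traj)
        assert np.all(lp == 0)
        assert np.all(rp == 0)

    def test_propensity_matches_planted_contacts(self, small_ensemble):
        traj, truth = small_ensemble
        lp, _, _, _ = binding_propensity(traj)
        planted = np.zeros(42)
        for fr in truth.contacts:
            touched = {a for a, _ in fr}
            for r in touched:
                planted[r] += 1
        planted /= traj.n_frames
        assert np.allclose(lp, planted)

    def test_bounded_by_bound_fraction(self, small_ensemble):
        traj, truth = small_ensemble
        lp, _, _, _ = binding_propensity(traj)
        frame_bound = np.array([len(fr) > 0 for fr in truth.contacts])
        assert np.all(lp <= frame_bound.mean() + 1e-12)


class TestSaltBridges:
    def test_close_pair_reported_with_distance(self):
        top, coords, sc0, sc1 = _pair_topology(3.2)
        found = salt_bridges(coords, top)
        assert len(found) == 1
        acid, base, d = found[0]
        assert (acid, base) == (0, 1)
        assert d == pytest.approx(3.2, abs=1e-6)

    def test_far_pair_absent(self):
        top, coords, _, _ = _pair_topology(4.5)
        assert salt_bridges(coords, top) == []

    def test_no_charged_residues_empty(self):
        top = build_peptide_topology("ALAV")
        coords = coil_coordinates(top)
        assert salt_bridges(coords, top) == []

    def test_bridges_are_contacts_at_contact_cutoff(self, small_ensemble):
        """Every salt bridge implies a heavy-atom contact (4 < 5.4 A)."""
        traj, _ = small_ensemble
        top = traj.topology
        lig = top.chain_residues("A")
        rec = top.chain_residues("R")
        for f in range(0, traj.n_frames, 10):
            bridges = salt_bridges(traj.xyz[f], top, lig, rec)
            if not bridges:
                continue
            contacts = residue_contact(traj.xyz[f], top, lig, rec,
                                       cutoff=5.4)
            for a, b, _ in bridges:
                la = a if a < len(lig) else b
                rb = (b if a < len(lig) else a) - len(lig)
                assert contacts[la, rb]


class TestHydrogenBonds:
    def test_hairpin_cross_strand_bonds_counted(self):
        top = build_peptide_topology(AB42_SEQUENCE)
        coords = plant_hairpin(coil_coordinates(top), top, (16, 22),
                               (29, 35))
        count, bonds = hydrogen_bonds(coords, top, list(range(16, 23)),
                                      list(range(29, 36)))
        assert count >= 2
        assert all(d != a for d, a, _, _ in bonds)

    def test_distance_gate(self):
        top, coords, _, _ = _pair_topology(5.0)
        count, _ = hydrogen_bonds(coords, top, [0], [1])
        assert count == 0

    def test_angle_gate(self):
        top = build_peptide_topology("SK")
        coords = coil_coordinates(top)
        idx0, idx1 = top.residue_atoms(0), top.residue_atoms(1)
        coords[idx1] += 200.0
        ca0 = idx0[top.atom_names[idx0] == "CA"][0]
        sc0 = idx0[top.atom_names[idx0] == "SC"][0]
        sc1 = idx1[top.atom_names[idx1] == "SC"][0]
        coords[ca0] = [0.0, 0, 0]
        coords[sc0] = [2.4, 0, 0]  # implied H along +x
        # acceptor at 3.0 A but 45 degrees off the H direction
        coords[sc1] = coords[sc0] + 3.0 * np.array(
            [np.cos(np.radians(45)), np.sin(np.radians(45)), 0])
        count, _ = hydrogen_bonds(coords, top, [0], [1])
        assert count == 0
        # same distance along the H direction is accepted
        coords[sc1] = coords[sc0] + [3.0, 0, 0]
        count, _ = hydrogen_bonds(coords, top, [0], [1])
        assert count == 1


class TestBetaRegions:
    def test_simple_rule_application(self):
        flags = np.zeros((6, 10), dtype=bool)
        flags[:3, 2:7] = True  # residues 2..6 beta in 3 clusters
        flags[:2, 8] = True    # residue 8 in only 2 clusters
        regions = beta_regions(flags, region_min_clusters=3)
        assert [(r.start, r.end) for r in regions] == [(2, 6)]

    def test_exactly_two_clusters_excluded(self):
        flags = np.zeros((6, 5), dtype=bool)
        flags[:2, 2] = True
        assert beta_regions(flags, region_min_clusters=3) == []

    def test_gap_with_support_bridged_gap_without_separates(self):
        flags = np.zeros((5, 12), dtype=bool)
        flags[:3, 1:4] = True
        flags[:2, 4] = True   # weak evidence -> bridged
        flags[:3, 5:7] = True
        flags[:3, 9:11] = True  # residue 7,8 bare -> separate region
        regions = beta_regions(flags, region_min_clusters=3)
        assert [(r.start, r.end) for r in regions] == [(1, 6), (9, 10)]

    def test_reference_strand_table_yields_five_regions(self):
        regions = beta_regions(cluster_strand_flags(),
                               region_min_clusters=3)
        spans = [(r.start + 1, r.end + 1) for r in regions]  # 1-based
        assert spans == [(2, 6), (10, 13), (15, 24), (27, 36), (38, 41)]
        assert [r.label for r in regions] == [
            "beta1", "beta2", "beta3", "beta4", "beta5"]

    def test_monotone_in_min_clusters(self):
        flags = cluster_strand_flags()
        sizes = []
        for k in (3, 4, 5, 6):
            regions = beta_regions(flags, region_min_clusters=k)
            covered = set()
            for r in regions:
                covered |= set(range(r.start, r.end + 1))
            sizes.append(covered)
        for lo, hi in zip(sizes[1:], sizes[:-1]):
            assert lo <= hi  # raising the threshold never enlarges coverage


class TestSheetAssociations:
    def test_planted_hairpin_association(self):
        top = build_peptide_topology(AB42_SEQUENCE)
        coords = plant_hairpin(coil_coordinates(top), top, (16, 22),
                               (29, 35))
        labels = assign_ss(coords, top)
        bonds = backbone_hbond_matrix(coords, top)
        pairs = list(zip(*np.nonzero(bonds)))
        regions = beta_regions(cluster_strand_flags(),
                               region_min_clusters=3)
        assoc = sheet_associations(labels, pairs, regions)
        assert ("beta3", "beta4") in assoc

    def test_all_coil_frame_empty(self):
        top = build_peptide_topology(AB42_SEQUENCE)
        coords = coil_coordinates(top)
        labels = assign_ss(coords, top)
        bonds = backbone_hbond_matrix(coords, top)
        pairs = list(zip(*np.nonzero(bonds)))
        regions = beta_regions(cluster_strand_flags(),
                               region_min_clusters=3)
        assert sheet_associations(labels, pairs, regions) == []

    def test_three_stranded_sheet_reports_both_pairs(self):
        # beta3-beta4 and beta4-beta5 each connected by two H-bonds,
        # beta3-beta5 by none: both hairpin pairs reported, no spurious pair
        regions = beta_regions(cluster_strand_flags(),
                               region_min_clusters=3)
        labels = np.full(42, "C", dtype="U1")
        for lo, hi in [(14, 23), (26, 35), (37, 40)]:
            labels[lo:hi + 1] = "E"
        pairs = [(16, 33), (33, 16), (18, 31),      # beta3 <-> beta4
                 (28, 39), (39, 28)]                # beta4 <-> beta5
        assoc = sheet_associations(labels, pairs, regions)
        assert assoc == [("beta3", "beta4"), ("beta4", "beta5")]


class TestRMSF:
    def _static_traj(self):
        top = build_peptide_topology("AAAAAA")
        coords = coil_coordinates(top)
        xyz = np.tile(coords, (20, 1, 1))
        return top, xyz

    def test_static_trajectory_zero(self):
        top, xyz = self._static_traj()
        fluct, _ = rmsf(Trajectory(top, xyz))
        assert np.allclose(fluct, 0.0, atol=1e-9)

    def test_rigid_motion_removed(self, rng):
        top, xyz = self._static_traj()
        for f in range(xyz.shape[0]):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                            [np.sin(theta), np.cos(theta), 0],
                            [0, 0, 1.0]])
            xyz[f] = xyz[f] @ rot.T + rng.uniform(-20, 20, 3)
        fluct, _ = rmsf(Trajectory(top, xyz))
        assert np.allclose(fluct, 0.0, atol=1e-6)

    def test_isotropic_jitter_closed_form(self, rng):
        top = build_peptide_topology("AAAAAAAAAA")
        coords = coil_coordinates(top)
        n_frames = 1000
        sigma = 0.5
        xyz = np.tile(coords, (n_frames, 1, 1))
        # jitter one residue's CA isotropically; keep the fit selection to
        # the unperturbed residues so superposition stays exact
        ca5 = top.residue_atoms(5)[
            top.atom_names[top.residue_atoms(5)] == "CA"][0]
        xyz[:, ca5, :] += rng.normal(0, sigma, size=(n_frames, 3))
        fit = [i for i in range(top.n_atoms) if i != ca5]
        fluct, residues = rmsf(Trajectory(top, xyz), selection=np.array(fit))
        expected = np.sqrt(3) * sigma
        assert fluct[5] == pytest.approx(expected, rel=0.05)
        assert np.allclose(np.delete(fluct, 5), 0.0, atol=1e-9)
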