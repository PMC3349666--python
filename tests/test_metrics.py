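"""Superposition, RMSD/RMSF, interaction detection, Qf, distances, populations."""

import numpy as np
import pytest

from crossbeta import (
    FluctuationSpec,
    Trajectory,
    ZipperGeometry,
    build_hexamer_topology,
    build_ideal_zipper,
    ca_rmsd,
    ca_rmsf,
    detect_hbonds,
    detect_native_contacts,
    extract_oligomer,
    generate_trajectory,
    interaction_population,
    intersheet_distance,
    interstrand_distance,
    kabsch_superpose,
    per_residue_average,
    qf,
    qf_series,
)
from crossbeta.metrics import InteractionRecord, compute_metric_series
from crossbeta.pdbio import Atom, Structure

from conftest import (
    brute_force_contacts,
    brute_force_hbonds,
    quaternion_rmsd,
    random_zipper_like_structure,
)


def _random_rigid(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-20, 20, 3)


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.standard_normal((12, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_pure_translation(self, rng):
        pts = rng.standard_normal((10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts + np.array([3.0, 4.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.standard_normal((15, 3)) * 5
        for _ in range(20):
            rot, trans = _random_rigid(rng)
            _, _, rmsd = kabsch_superpose(pts, pts @ rot.T + trans)
            assert rmsd < 1e-8

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(20):
            ref = rng.standard_normal((10, 3)) * 4
            mob = ref + rng.standard_normal((10, 3)) * 0.8
            rot, trans = _random_rigid(rng)
            mob = mob @ rot.T + trans
            _, _, rmsd = kabsch_superpose(ref, mob)
            assert rmsd == pytest.approx(quaternion_rmsd(ref, mob), abs=1e-6)

    def test_proper_rotation_only(self, rng):
        ref = rng.standard_normal((8, 3))
        mob = ref.copy()
        mob[:, 0] *= -1  # mirror image
        rot, _, _ = kabsch_superpose(ref, mob)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_size_mismatch_and_collinear_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 0.5]))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestRmsdRmsf:
    def test_static_trajectory_zero(self, ideal_hexamer):
        traj = generate_trajectory(
            ideal_hexamer, FluctuationSpec(per_residue_sigma=(0.0,) * 6, n_frames=4)
        )
        np.testing.assert_allclose(ca_rmsd(traj), 0.0, atol=1e-10)
        assert (ca_rmsf(traj)["rmsf"] < 1e-10).all()

    def test_rigid_motion_invariance(self, ideal_hexamer, rng):
        frames = []
        for _ in range(5):
            rot, trans = _random_rigid(rng)
            frames.append(ideal_hexamer.coords @ rot.T + trans)
        traj = Trajectory(structure=ideal_hexamer, coords=np.array(frames))
        np.testing.assert_allclose(ca_rmsd(traj), 0.0, atol=1e-8)

    def test_translated_strand_matches_oracle(self, rng):
        # 6-strand CA-only toy; one strand moved 10 A, RMSD checked against
        # the quaternion oracle on the same selection
        atoms = []
        for c, chain in enumerate("ABCDEF"):
            for i in range(1, 7):
                atoms.append(
                    Atom("CA", "C", 12.011, i, "ALA", chain,
                         np.array([3.5 * (i - 1), 4.8 * c, 0.0]))
                )
        s = Structure(atoms=atoms)
        moved = s.coords.copy()
        moved[30:] += np.array([0.0, 0.0, 10.0])
        traj = Trajectory(structure=s, coords=moved[None])
        expected = quaternion_rmsd(s.coords, moved)
        assert ca_rmsd(traj)[0] == pytest.approx(expected, abs=1e-9)
        assert expected > 2.5  # the displacement is not absorbed by the fit

    def test_isotropic_rmsf_closed_form(self, ideal_hexamer):
        sigma = 0.5
        traj = generate_trajectory(
            ideal_hexamer,
            FluctuationSpec(per_residue_sigma=(sigma,) * 6, n_frames=2000, seed=11),
        )
        rmsf = ca_rmsf(traj, superpose=False)["rmsf"]
        assert rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_terminal_profile_recovered(self, ideal_hexamer):
        # strictly distinct amplitudes, largest at the termini
        profile = (0.7, 0.5, 0.3, 0.2, 0.4, 0.6)
        traj = generate_trajectory(
            ideal_hexamer,
            FluctuationSpec(per_residue_sigma=profile, n_frames=2000, seed=5),
        )
        rmsf = ca_rmsf(traj, superpose=False)
        by_pos = rmsf.groupby("residue_position")["rmsf"].mean()
        from scipy.stats import spearmanr

        rho, _ = spearmanr(by_pos.values, profile)
        assert rho == pytest.approx(1.0)

    def test_rmsf_needs_two_frames(self, ideal_hexamer):
        traj = Trajectory(structure=ideal_hexamer, coords=ideal_hexamer.coords[None])
        with pytest.raises(ValueError):
            ca_rmsf(traj)


class TestHbonds:
    def test_criterion_boundary(self, hexamer_topology):
        def pair_structure(dist):
            atoms = [
                Atom("N", "N", 14.007, 1, "VAL", "A", np.zeros(3)),
                Atom("CA", "C", 12.011, 1, "VAL", "A", np.array([1.5, 0, 0])),
                Atom("O", "O", 15.999, 1, "VAL", "B", np.array([0.0, dist, 0.0])),
                Atom("CA", "C", 12.011, 1, "VAL", "B", np.array([1.5, dist, 0.0])),
            ]
            return Structure(atoms=atoms)

        topo = extract_oligomer(hexamer_topology, "2-0").renumbered()
        assert len(detect_hbonds(pair_structure(3.4), topo)) == 1
        assert len(detect_hbonds(pair_structure(3.6), topo)) == 0
        assert len(detect_hbonds(pair_structure(3.5), topo)) == 0  # strict <

    def test_same_chain_pairs_excluded(self, hexamer_topology):
        atoms = [
            Atom("N", "N", 14.007, 1, "VAL", "A", np.zeros(3)),
            Atom("CA", "C", 12.011, 1, "VAL", "A", np.array([1.0, 0, 0])),
            Atom("O", "O", 15.999, 2, "GLU", "A", np.array([2.0, 0, 0])),
            Atom("CA", "C", 12.011, 2, "GLU", "A", np.array([3.0, 0, 0])),
            Atom("CA", "C", 12.011, 1, "VAL", "B", np.array([0, 30.0, 0])),
        ]
        topo = extract_oligomer(hexamer_topology, "2-0").renumbered()
        assert detect_hbonds(Structure(atoms=atoms), topo) == []

    def test_ideal_hexamer_matches_brute_force(
        self, ideal_hexamer, hexamer_topology
    ):
        records = detect_hbonds(ideal_hexamer, hexamer_topology)
        assert {r.participants for r in records} == brute_force_hbonds(ideal_hexamer)
        assert all(r.interaction_class == "interstrand" for r in records)


class TestNativeContacts:
    def test_classification_via_topology(self, ideal_hexamer, hexamer_topology):
        records = detect_native_contacts(ideal_hexamer, hexamer_topology)
        classes = {r.interaction_class for r in records}
        assert classes == {"interstrand", "intersheet"}
        # strand pair (1,4) contacts are intersheet
        inter = [
            r for r in records
            if {p[0] for p in r.participants} == {"A", "D"}
        ]
        assert inter and all(r.interaction_class == "intersheet" for r in inter)

    def test_adjacent_residues_excluded(self, hexamer_topology):
        # two side chains on one chain, residues 1 and 2, arbitrarily close
        atoms = [
            Atom("CA", "C", 12.011, 1, "VAL", "A", np.zeros(3)),
            Atom("CB", "C", 12.011, 1, "VAL", "A", np.array([0.5, 0, 0])),
            Atom("CA", "C", 12.011, 2, "GLU", "A", np.array([1.0, 0, 0])),
            Atom("CB", "C", 12.011, 2, "GLU", "A", np.array([0.6, 0, 0])),
            Atom("CA", "C", 12.011, 1, "VAL", "B", np.array([0, 30.0, 0])),
        ]
        topo = extract_oligomer(hexamer_topology, "2-0").renumbered()
        assert detect_native_contacts(Structure(atoms=atoms), topo) == []

    def test_matches_brute_force_on_ideal(self, ideal_hexamer, hexamer_topology):
        records = detect_native_contacts(ideal_hexamer, hexamer_topology)
        assert {r.participants for r in records} == brute_force_contacts(ideal_hexamer)

    def test_randomized_fixtures_match_brute_force(self, rng, hexamer_topology):
        label_for = {2: "2-0", 3: "2-1", 4: "2-2", 5: "3-2", 6: "3-3"}
        for _ in range(10):
            s = random_zipper_like_structure(rng)
            topo = extract_oligomer(
                hexamer_topology, label_for[s.n_chains]
            ).renumbered()
            got = {r.participants for r in detect_native_contacts(s, topo)}
            assert got == brute_force_contacts(s)
            got_hb = {r.participants for r in detect_hbonds(s, topo)}
            assert got_hb == brute_force_hbonds(s)

    def test_intersheet_cutoff_override(self, ideal_hexamer, hexamer_topology):
        loose = detect_native_contacts(ideal_hexamer, hexamer_topology, 6.5)
        tight = detect_native_contacts(
            ideal_hexamer, hexamer_topology, 6.5, intersheet_cutoff=5.0
        )
        n_intersheet = sum(r.interaction_class == "intersheet" for r in loose)
        assert n_intersheet > 0
        assert sum(r.interaction_class == "intersheet" for r in tight) < n_intersheet
        # interstrand records unaffected by the override
        assert sum(r.interaction_class == "interstrand" for r in tight) == sum(
            r.interaction_class == "interstrand" for r in loose
        )


class TestQf:
    def test_native_frame_is_one(self, ideal_hexamer, hexamer_topology):
        records = detect_native_contacts(ideal_hexamer, hexamer_topology)
        assert qf(ideal_hexamer, records) == 1.0

    def test_blown_apart_is_zero(self, ideal_hexamer, hexamer_topology):
        records = detect_native_contacts(ideal_hexamer, hexamer_topology)
        coords = ideal_hexamer.coords
        for k, chain in enumerate(ideal_hexamer.chain_ids):
            mask = np.array([a.chain_id == chain for a in ideal_hexamer.atoms])
            coords[mask] += k * np.array([50.0, 50.0, 0.0])
        assert qf(ideal_hexamer.with_coords(coords), records) == 0.0

    def test_half_broken_is_half(self, hexamer_topology):
        # 2-0 dimer: native contacts are the six register pairs; displace
        # three of chain B's side chains far away -> Qf exactly 0.5
        topo = extract_oligomer(hexamer_topology, "2-0").renumbered()
        s = build_ideal_zipper(ZipperGeometry(), topo)
        records = detect_native_contacts(s, topo)
        assert len(records) == 6
        coords = s.coords
        for i, a in enumerate(s.atoms):
            if a.chain_id == "B" and a.name == "CB" and a.residue_position <= 3:
                coords[i] += np.array([0.0, 0.0, 99.0])
        assert qf(s.with_coords(coords), records) == 0.5

    def test_series_matches_scalar(self, ideal_hexamer, hexamer_topology):
        records = detect_native_contacts(ideal_hexamer, hexamer_topology)
        traj = generate_trajectory(
            ideal_hexamer, FluctuationSpec(n_frames=5, seed=9)
        )
        series = qf_series(traj, records)
        for t in range(5):
            assert series[t] == pytest.approx(qf(traj.frame(t), records))

    def test_empty_native_list_rejected(self, ideal_hexamer):
        with pytest.raises(ValueError):
            qf(ideal_hexamer, [])

    def test_monotone_under_uniform_expansion(self, ideal_hexamer, hexamer_topology):
        records = detect_native_contacts(ideal_hexamer, hexamer_topology)
        center = ideal_hexamer.coords.mean(axis=0)
        prev = 1.0
        for scale in (1.0, 1.1, 1.3, 1.6, 2.5, 5.0):
            frame = ideal_hexamer.with_coords(
                (ideal_hexamer.coords - center) * scale + center
            )
            cur = qf(frame, records)
            assert cur <= prev + 1e-12
            prev = cur


class TestDistances:
    def test_drifted_strand_adds_along_axis(self, hexamer_topology):
        topo = extract_oligomer(hexamer_topology, "2-0").renumbered()
        s = build_ideal_zipper(ZipperGeometry(), topo)
        coords = s.coords
        mask = np.array([a.chain_id == "B" for a in s.atoms])
        coords[mask] += np.array([0.0, 4.0, 0.0])
        assert interstrand_distance(s.with_coords(coords), topo) == pytest.approx(
            8.8, abs=1e-9
        )

    def test_no_interstrand_pairs_not_applicable(self, hexamer_topology):
        topo = extract_oligomer(hexamer_topology, "1-1").renumbered()
        s = build_ideal_zipper(ZipperGeometry(), topo)
        assert np.isnan(interstrand_distance(s, topo))
        assert intersheet_distance(s, topo) == pytest.approx(10.0, abs=1e-9)

    def test_intersheet_translation_invariance(
        self, ideal_hexamer, hexamer_topology
    ):
        shifted = ideal_hexamer.with_coords(
            ideal_hexamer.coords + np.array([3.0, -7.0, 2.0])
        )
        assert intersheet_distance(shifted, hexamer_topology) == pytest.approx(
            10.0, abs=1e-9
        )

    def test_interstrand_matches_brute_force(self, rng, hexamer_topology):
        # randomized coordinates: compare against an explicit loop over the
        # four stacked pairs and their register-paired residues
        s = build_ideal_zipper(ZipperGeometry(), hexamer_topology)
        coords = s.coords + rng.standard_normal(s.coords.shape)
        frame = s.with_coords(coords)
        ca = {
            (a.chain_id, a.residue_position): coords[i]
            for i, a in enumerate(s.atoms)
            if a.name == "CA"
        }
        chain_of = {k + 1: ch for k, ch in enumerate(s.chain_ids)}
        acc = []
        for sa, sb in sorted(hexamer_topology.interstrand_pairs):
            acc.append(
                np.mean(
                    [
                        np.linalg.norm(ca[(chain_of[sa], i)] - ca[(chain_of[sb], i)])
                        for i in range(1, 7)
                    ]
                )
            )
        assert interstrand_distance(frame, hexamer_topology) == pytest.approx(
            float(np.mean(acc)), abs=1e-9
        )


class TestPopulations:
    def _contact_record(self, cutoff=6.5):
        return InteractionRecord(
            kind="contact",
            interaction_class="interstrand",
            participants=(("A", 1), ("B", 1)),
            native_distance=5.0,
            cutoff=cutoff,
        )

    def _two_residue_structure(self):
        atoms = [
            Atom("CA", "C", 12.011, 1, "VAL", "A", np.zeros(3)),
            Atom("CB", "C", 12.011, 1, "VAL", "A", np.array([1.0, 0, 0])),
            Atom("CA", "C", 12.011, 1, "VAL", "B", np.array([0.0, 5.0, 0])),
            Atom("CB", "C", 12.011, 1, "VAL", "B", np.array([1.0, 5.0, 0])),
        ]
        return Structure(atoms=atoms)

    def test_always_present_is_stable(self):
        s = self._two_residue_structure()
        traj = Trajectory(structure=s, coords=np.repeat(s.coords[None], 10, axis=0))
        table = interaction_population([traj], [self._contact_record()])
        assert table.loc[0, "population"] == 1.0
        assert bool(table.loc[0, "stable"])

    def test_exactly_forty_percent_is_not_stable(self):
        s = self._two_residue_structure()
        coords = np.repeat(s.coords[None], 100, axis=0)
        coords[40:, 2:, 2] += 50.0  # chain B out of reach in 60 of 100 frames
        traj = Trajectory(structure=s, coords=coords)
        table = interaction_population([traj], [self._contact_record()])
        assert table.loc[0, "population"] == pytest.approx(0.40)
        assert not bool(table.loc[0, "stable"])  # strictly greater than 40%

    def test_breakage_probability_recovered(self, rng):
        p_break = 0.3
        n = 2000
        s = self._two_residue_structure()
        coords = np.repeat(s.coords[None], n, axis=0)
        broken = rng.random(n) < p_break
        coords[broken, 2:, 2] += 50.0
        traj = Trajectory(structure=s, coords=coords)
        table = interaction_population([traj], [self._contact_record()])
        ci99 = 2.576 * np.sqrt(p_break * (1 - p_break) / n)
        assert abs(table.loc[0, "population"] - (1 - p_break)) < ci99

    def test_pooling_over_trajectories(self):
        s = self._two_residue_structure()
        present = Trajectory(structure=s, coords=np.repeat(s.coords[None], 30, axis=0))
        far = s.coords.copy()
        far[2:, 2] += 50.0
        absent = Trajectory(structure=s, coords=np.repeat(far[None], 70, axis=0))
        table = interaction_population([present, absent], [self._contact_record()])
        assert table.loc[0, "population"] == pytest.approx(0.30)

    def test_burn_in_discards_leading_frames(self):
        s = self._two_residue_structure()
        coords = np.repeat(s.coords[None], 10, axis=0)
        coords[:5, 2:, 2] += 50.0  # broken only during the first half
        traj = Trajectory(structure=s, coords=coords)
        table = interaction_population([traj], [self._contact_record()], burn_in=0.5)
        assert table.loc[0, "population"] == 1.0


class TestPerResidueAverage:
    def test_no_interactions_is_zero(self):
        np.testing.assert_array_equal(per_residue_average([], 6), np.zeros(6))

    def test_single_permanent_contact_hand_count(self):
        rec = InteractionRecord(
            kind="contact",
            interaction_class="intersheet",
            participants=(("A", 1), ("B", 4)),
            native_distance=5.0,
            cutoff=6.5,
            presence=np.ones(10, dtype=bool),
        )
        out = per_residue_average([rec], n_chains=6)
        expected = np.zeros(6)
        expected[0] = expected[3] = 1 / 6
        np.testing.assert_allclose(out, expected)

    def test_time_average_invariant_to_frame_count(self):
        short = InteractionRecord(
            "contact", "interstrand", (("A", 2), ("B", 2)), 5.0, 6.5,
            presence=np.array([True, False]),
        )
        long = InteractionRecord(
            "contact", "interstrand", (("A", 2), ("B", 2)), 5.0, 6.5,
            presence=np.array([True, False] * 50),
        )
        np.testing.assert_allclose(
            per_residue_average([short], 6), per_residue_average([long], 6)
        )

    def test_same_position_endpoints_count_twice(self):
        rec = InteractionRecord(
            "contact", "interstrand", (("A", 3), ("B", 3)), 4.8, 6.5,
            presence=np.ones(4, dtype=bool),
        )
        out = per_residue_average([rec], n_chains=6)
        assert out[2] == pytest.approx(2 / 6)


class TestMetricSeries:
    def test_bundle_shapes_and_csv_columns(self, ideal_hexamer, hexamer_topology):
        traj = generate_trajectory(
            ideal_hexamer, FluctuationSpec(n_frames=6, seed=4), hexamer_topology
        )
        series = compute_metric_series(traj, hexamer_topology)
        df = series.to_frame()
        assert list(df.columns) == [
            "time_ns", "rmsd", "qf", "interstrand_distance", "intersheet_distance",
        ]
        assert len(df) == 6
        assert ((series.qf >= 0) & (series.qf <= 1)).all()
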