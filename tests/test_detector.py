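import dataclasses

import numpy as np
import pytest

from conftest import apply_rigid, rigid_transform
from oracle import brute_force_scan

from nacscan.detector import (
    MissingHydrogensError,
    SiteResolutionError,
    detect_w1,
    detect_w2,
    find_activators,
    reports_to_dataframe,
    scan,
    select_site_waters,
)
from nacscan.geometry import AngleWindow
from nacscan.synthetic import (
    PlantSchedule,
    decoy_spec,
    default_site,
    generate,
    w1_spec,
    w2_spec,
)
from nacscan.trajectory import AtomRecord, Frame, Trajectory


def _got_sets(reports):
    return [
        ({h.water for h in r.w1_hits}, {(h.w1_water, h.w2_water) for h in r.w2_hits})
        for r in reports
    ]


class TestSelectSiteWaters:
    def test_never_near_water_excluded(self, site):
        sched = PlantSchedule(2, [[decoy_spec("far", "distance")]] * 2)
        traj, _ = generate(sched)
        assert select_site_waters(traj, site) == set()

    def test_once_near_water_included(self, site):
        # near C in exactly one of five frames is enough
        sched = PlantSchedule(5, [[], [], [w1_spec("A")], [], []])
        traj, truth = generate(sched)
        assert select_site_waters(traj, site) == {truth.water_ids["A"]}

    def test_matches_generator_ground_truth(self, mixed_trajectory, site):
        traj, truth = mixed_trajectory
        assert select_site_waters(traj, site) == set(truth.site_waters)


class TestDetectW1:
    def test_no_candidates_no_hits(self, site):
        sched = PlantSchedule(1, [[w1_spec("A")]])
        traj, _ = generate(sched)
        assert detect_w1(traj.frames[0], site, candidate_waters=[]) == []

    def test_planted_water_reported_with_exact_values(self, site):
        sched = PlantSchedule(1, [[w1_spec("A", distance=3.0, angle_deg=106.0)]])
        traj, truth = generate(sched)
        hits = detect_w1(traj.frames[0], site)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.water == truth.water_ids["A"]
        assert hit.o_c_distance == pytest.approx(3.0, abs=1e-9)
        assert hit.bd_angle == pytest.approx(106.0, abs=1e-9)
        assert hit.orientation_ok

    @pytest.mark.parametrize("violated", ["distance", "angle", "orientation"])
    def test_single_criterion_decoys_rejected(self, site, violated):
        sched = PlantSchedule(1, [[decoy_spec("D", violated)]])
        traj, _ = generate(sched)
        assert detect_w1(traj.frames[0], site) == []

    def test_angle_just_outside_closed_window(self, site):
        sched = PlantSchedule(1, [[w1_spec("A", angle_deg=104.0)]])
        traj, truth = generate(sched)
        # outside the closed [105,107] window: not detected and not labeled
        assert detect_w1(traj.frames[0], site) == []
        assert truth.frames[0].w1 == frozenset()

    @pytest.mark.parametrize("angle_deg", [105.0, 107.0])
    def test_window_bounds_inclusive(self, site, angle_deg):
        sched = PlantSchedule(1, [[w1_spec("A", angle_deg=angle_deg)]])
        traj, _ = generate(sched)
        assert len(detect_w1(traj.frames[0], site)) == 1

    def test_hits_sorted_by_distance(self, site):
        sched = PlantSchedule(
            1, [[w1_spec("B", distance=3.3), w1_spec("A", distance=2.9)]]
        )
        traj, _ = generate(sched)
        hits = detect_w1(traj.frames[0], site)
        assert [h.o_c_distance for h in hits] == sorted(h.o_c_distance for h in hits)
        assert len(hits) == 2

    def test_missing_hydrogens_error_and_skip(self, site):
        sched = PlantSchedule(1, [[w1_spec("A")]])
        traj, _ = generate(sched)
        # strip the water hydrogens
        atoms = [a for a in traj.frames[0].atoms if a.element != "H"]
        dry = Trajectory([Frame(index=0, atoms=atoms)])
        with pytest.raises(MissingHydrogensError):
            detect_w1(dry.frames[0], site)
        lax = dataclasses.replace(site, on_missing_hydrogens="skip")
        assert detect_w1(dry.frames[0], lax) == []

    def test_ambiguous_carbonyl_rejected(self, site):
        sched = PlantSchedule(1, [[w1_spec("A")]])
        traj, _ = generate(sched)
        dup = traj.frames[0].atoms[0]
        extra = dataclasses.replace(dup, atom_serial=999)
        frame = Frame(index=0, atoms=list(traj.frames[0].atoms) + [extra])
        with pytest.raises(SiteResolutionError):
            detect_w1(frame, site)


class TestDetectW2:
    def test_far_water_not_assisting(self, site):
        sched = PlantSchedule(1, [[w1_spec("A"), w2_spec("B", distance=4.0)]])
        traj, _ = generate(sched)
        w1 = detect_w1(traj.frames[0], site)[0]
        assert detect_w2(traj.frames[0], w1, site) == []

    def test_donor_water_detected(self, site):
        sched = PlantSchedule(1, [[w1_spec("A"), w2_spec("B", distance=2.8)]])
        traj, truth = generate(sched)
        w1 = detect_w1(traj.frames[0], site)[0]
        hits = detect_w2(traj.frames[0], w1, site)
        assert len(hits) == 1
        assert hits[0].w2_water == truth.water_ids["B"]
        assert hits[0].oo_distance == pytest.approx(2.8, abs=1e-9)

    def test_non_donor_rejected_unless_orientation_disabled(self, site):
        sched = PlantSchedule(
            1, [[w1_spec("A"), w2_spec("B", distance=2.8, orientation="non-donor")]]
        )
        traj, _ = generate(sched)
        w1 = detect_w1(traj.frames[0], site)[0]
        assert detect_w2(traj.frames[0], w1, site) == []
        lax = dataclasses.replace(site, require_w2_orientation=False)
        assert len(detect_w2(traj.frames[0], w1, lax)) == 1

    def test_w1_never_its_own_assistant(self, site):
        sched = PlantSchedule(1, [[w1_spec("A"), w2_spec("B")]])
        traj, _ = generate(sched)
        w1 = detect_w1(traj.frames[0], site)[0]
        for hit in detect_w2(traj.frames[0], w1, site):
            assert hit.w2_water != w1.water

    def test_wrong_frame_rejected(self, site):
        sched = PlantSchedule(2, [[w1_spec("A")], [w1_spec("A")]])
        traj, _ = generate(sched)
        w1 = detect_w1(traj.frames[0], site)[0]
        with pytest.raises(ValueError):
            detect_w2(traj.frames[1], w1, site)


class TestFindActivators:
    def test_no_protein_near_empty(self, site):
        sched = PlantSchedule(1, [[w1_spec("A"), w2_spec("B")]])
        traj, truth = generate(sched)
        assert find_activators(traj.frames[0], truth.water_ids["B"], site) == []

    def test_planted_carboxylate_oxygen_found(self, site):
        sched = PlantSchedule(1, [[w1_spec("A"), w2_spec("B", activator_distance=3.0)]])
        traj, truth = generate(sched)
        contacts = find_activators(traj.frames[0], truth.water_ids["B"], site)
        assert len(contacts) == 1
        assert contacts[0].residue_name == "ASP"
        assert contacts[0].atom_name == "OD1"
        assert contacts[0].distance == pytest.approx(3.0, abs=1e-9)

    def test_multiple_contacts_distance_sorted(self, site):
        sched = PlantSchedule(1, [[w1_spec("A"), w2_spec("B", activator_distance=3.2)]])
        traj, truth = generate(sched)
        # add a closer backbone nitrogen by hand
        w2_o = next(
            a.position
            for a in traj.frames[0].atoms
            if (a.residue_name, a.residue_seq, a.chain_id) == truth.water_ids["B"]
            and a.element == "O"
        )
        extra = AtomRecord(998, "N", "GLY", 95, "", "N", w2_o + np.array([0, 0, 2.5]))
        frame = Frame(index=0, atoms=list(traj.frames[0].atoms) + [extra])
        contacts = find_activators(frame, truth.water_ids["B"], site)
        assert [c.atom_name for c in contacts] == ["N", "OD1"]
        assert contacts[0].distance < contacts[1].distance


class TestScan:
    def test_empty_everywhere(self, site):
        sched = PlantSchedule(4, [[decoy_spec("D", "angle")], [], [], []])
        traj, _ = generate(sched)
        reports = scan(traj, site)
        assert len(reports) == 4
        assert all(not r.has_w1 and not r.has_w1w2 for r in reports)

    def test_planted_schedule_flags(self, site):
        frames = [[] for _ in range(8)]
        frames[2] = [w1_spec("A")]
        frames[5] = [w1_spec("A")]
        frames[7] = [w1_spec("A"), w2_spec("B")]
        sched = PlantSchedule(8, frames)
        traj, _ = generate(sched)
        reports = scan(traj, site)
        assert [r.has_w1 for r in reports] == [
            False, False, True, False, False, True, False, True,
        ]
        assert [r.has_w1w2 for r in reports] == [False] * 7 + [True]

    def test_scan_equals_per_frame_composition(self, mixed_trajectory, site):
        traj, _ = mixed_trajectory
        reports = scan(traj, site)
        site_waters = select_site_waters(traj, site)
        for frame, rep in zip(traj.frames, reports):
            w1 = detect_w1(frame, site, candidate_waters=site_waters)
            assert tuple(w1) == rep.w1_hits
            w2 = []
            for h in w1:
                w2.extend(detect_w2(frame, h, site))
            assert tuple(w2) == rep.w2_hits

    def test_deterministic_rescan(self, mixed_trajectory, site):
        traj, _ = mixed_trajectory
        assert scan(traj, site) == scan(traj, site)

    def test_matches_brute_force_oracle(self, site):
        # irregular schedule incl. jitter: oracle and detector must agree
        rng = np.random.default_rng(42)
        frames = []
        for i in range(12):
            specs = []
            if rng.random() < 0.6:
                specs.append(w1_spec("A", distance=2.8 + 0.4 * rng.random(),
                                     angle_deg=105.2 + 1.6 * rng.random()))
                if rng.random() < 0.5:
                    specs.append(w2_spec("B", distance=2.6 + 0.6 * rng.random()))
            if rng.random() < 0.4:
                specs.append(decoy_spec("D", "orientation"))
            frames.append(specs)
        sched = PlantSchedule(12, frames, jitter_sigma=0.05, seed=9)
        traj, _ = generate(sched)
        reports = scan(traj, site)
        assert _got_sets(reports) == brute_force_scan(traj, site)

    def test_rigid_motion_invariance(self, mixed_trajectory, site):
        traj, _ = mixed_trajectory
        base = scan(traj, site)
        rng = np.random.default_rng(3)
        q, t = rigid_transform(rng)
        moved = scan(apply_rigid(traj, q, t), site)
        for r0, r1 in zip(base, moved):
            assert [h.water for h in r0.w1_hits] == [h.water for h in r1.w1_hits]
            for h0, h1 in zip(r0.w1_hits, r1.w1_hits):
                assert abs(h0.o_c_distance - h1.o_c_distance) < 1e-6
                assert abs(h0.bd_angle - h1.bd_angle) < 1e-6
            assert [(h.w1_water, h.w2_water) for h in r0.w2_hits] == [
                (h.w1_water, h.w2_water) for h in r1.w2_hits
            ]

    @pytest.mark.parametrize(
        "tighten, loosen",
        [
            ({"w1_dist_cutoff": 3.0}, {"w1_dist_cutoff": 4.0}),
            ({"bd_window": AngleWindow(105.5, 106.5)}, {"bd_window": AngleWindow(100.0, 112.0)}),
            ({"w2_dist_cutoff": 2.7}, {"w2_dist_cutoff": 4.5}),
        ],
    )
    def test_cutoff_monotonicity(self, mixed_trajectory, site, tighten, loosen):
        traj, _ = mixed_trajectory
        tight = scan(traj, dataclasses.replace(site, **tighten))
        base = scan(traj, site)
        loose = scan(traj, dataclasses.replace(site, **loosen))
        for rt, rb, rl in zip(tight, base, loose):
            assert len(rt.w1_hits) <= len(rb.w1_hits) <= len(rl.w1_hits)
            assert len(rt.w2_hits) <= len(rb.w2_hits) <= len(rl.w2_hits)


class TestReportTable:
    def test_dataframe_has_one_row_per_hit_with_1based_frames(self, mixed_trajectory, site):
        traj, _ = mixed_trajectory
        reports = scan(traj, site)
        df = reports_to_dataframe(reports)
        n_hits = sum(len(r.w1_hits) + len(r.w2_hits) for r in reports)
        assert len(df) == n_hits
        assert df["frame"].min() >= 1
        assert set(df["role"]) <= {"W1", "W2"}
        # activator annotations survive flattening
        w2_rows = df[df["role"] == "W2"]
        assert any(w2_rows["activators"].str.contains("ASP", na=False))
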