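"""Simulator: determinism, modality masking, physical sanity, splits, projection."""

import math

import numpy as np
import pytest

from orbench.simulate import (
    DEFAULT_PROFILES,
    MODALITY_FLAGS,
    ModalityProfile,
    SimConfig,
    ViewGeometry,
    assign_splits,
    project_to_views,
    simulate_case,
)


def test_fixed_seed_gives_byte_identical_timelines():
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=25, seed=3)
    a = simulate_case(cfg, "mmor-like", 0)
    b = simulate_case(cfg, "mmor-like", 0)
    assert a.to_json() == b.to_json()


def test_different_seeds_differ():
    a = simulate_case(SimConfig(timepoints_per_case=25, seed=3), "mmor-like", 0)
    b = simulate_case(SimConfig(timepoints_per_case=25, seed=4), "mmor-like", 0)
    assert a.to_json() != b.to_json()


def test_timepoint_count_and_strictly_increasing_time():
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=50, seed=1)
    tl = simulate_case(cfg, "4dor-like", 0)
    assert len(tl.records) == 50
    ts = [r.t for r in tl.records]
    assert all(a < b for a, b in zip(ts, ts[1:]))


def test_unknown_source_tag_is_configuration_error():
    with pytest.raises(KeyError):
        simulate_case(SimConfig(seed=0), "no-such-source", 0)


@pytest.mark.parametrize("tag", sorted(DEFAULT_PROFILES))
def test_modality_masking_disabled_fields_absent(tag):
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=15, seed=9)
    profile = DEFAULT_PROFILES[tag]
    tl = simulate_case(cfg, tag, 0)
    field_of = {
        "scene_graphs": "triplets",
        "phases": "phase",
        "robot_log": "robot",
        "gaze": "gaze",
        "monitor_text": "monitor_text",
        "audio_transcript": "transcript_tail",
    }
    for flag, fieldname in field_of.items():
        if not profile.flag(flag):
            assert all(getattr(r, fieldname) is None for r in tl.records)
    if not profile.points_3d:
        assert all(e.position_3d is None for r in tl.records for e in r.entities)
    if not profile.attributes:
        assert all(not e.attributes for r in tl.records for e in r.entities)


def test_physical_sanity_positions_and_boxes_in_bounds():
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=30, seed=21)
    tl = simulate_case(cfg, "mmor-like", 0)
    ex, ey, ez = cfg.room_extent
    w, h = cfg.image_size
    for r in tl.records:
        for e in r.entities:
            if e.position_3d is not None:
                x, y, z = e.position_3d
                assert -ex / 2 <= x <= ex / 2 and -ey / 2 <= y <= ey / 2 and 0 <= z <= ez
            for box in e.boxes_2d.values():
                x1, y1, x2, y2 = box
                assert 0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h


def test_phase_progress_monotone_within_phase_and_contiguous_partition():
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=40, seed=2)
    tl = simulate_case(cfg, "mvor-like", 0)
    # spans partition the timeline contiguously
    for (p1, a1, b1), (p2, a2, b2) in zip(tl.phase_spans, tl.phase_spans[1:]):
        assert math.isclose(b1, a2)
    last_phase, last_prog = None, -1.0
    for r in tl.records:
        assert 0.0 <= r.phase_progress <= 100.0
        if r.phase == last_phase:
            assert r.phase_progress >= last_prog
        last_phase, last_prog = r.phase, r.phase_progress


def test_robot_fsm_advances_through_fixed_sequence():
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=40, seed=5)
    tl = simulate_case(cfg, "mmor-like", 0)
    indices = [r.robot.step_index for r in tl.records]
    assert all(a <= b for a, b in zip(indices, indices[1:]))
    for r in tl.records:
        assert r.robot.current_step == tl.robot_steps[r.robot.step_index]
        assert r.robot.completed_steps == tl.robot_steps[: r.robot.step_index]
        assert r.robot.current_step not in r.robot.completed_steps


def test_sterility_breach_occurs_in_some_mmor_cases():
    cfg = SimConfig(n_cases_per_source=10, timepoints_per_case=20, seed=13, breach_fraction=0.8)
    breaches = 0
    for i in range(10):
        tl = simulate_case(cfg, "mmor-like", i)
        if any(
            (s, p) == ("head_surgeon", "touching")
            for r in tl.records
            for (s, p, o) in r.triplets
        ):
            breaches += 1
    assert breaches >= 1


def test_box_motion_is_continuous():
    """An entity's reference-view box center moves a bounded amount per step."""
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=30, seed=17)
    tl = simulate_case(cfg, "4dor-like", 0)
    # bound: focal * max 3D step / min depth, padded for clipping at borders
    bound = 260.0 * 0.25 / 1.0 + 40
    prev = {}
    for r in tl.records:
        for e in r.entities:
            box = e.boxes_2d.get("view0")
            if box is None:
                continue
            c = ((box[0] + box[2]) / 2, (box[1] + box[3]) / 2)
            if e.entity_id in prev:
                d = math.dist(prev[e.entity_id], c)
                assert d <= bound
            prev[e.entity_id] = c


# --- projection -------------------------------------------------------------

def test_projection_center_point_maps_to_image_midpoint():
    view = ViewGeometry(camera=(0.0, 0.0, 4.0), focal_px=100.0, image_size=(200, 200))
    boxes = project_to_views((0.0, 0.0, 1.0), (0.4, 0.4, 1.7), [view])
    x1, y1, x2, y2 = boxes["view0"]
    assert abs((x1 + x2) / 2 - 100) <= 1 and abs((y1 + y2) / 2 - 100) <= 1


def test_projection_matches_pinhole_arithmetic():
    # camera at (0,0,4), f=100, principal point (150,150):
    # point (1,0,2) -> depth 2, u = 100*1/2 + 150 = 200, v = 150
    view = ViewGeometry(camera=(0.0, 0.0, 4.0), focal_px=100.0, image_size=(300, 300))
    boxes = project_to_views((1.0, 0.0, 2.0), (0.2, 0.2, 0.2), [view])
    x1, y1, x2, y2 = boxes["view0"]
    assert abs((x1 + x2) / 2 - 200) <= 1
    assert abs((y1 + y2) / 2 - 150) <= 1
    # half-size = f*extent/2/depth = 100*0.1/2 = 5 px
    assert 8 <= (x2 - x1) <= 12


def test_projection_clips_near_border_but_keeps_valid_box():
    view = ViewGeometry(camera=(0.0, 0.0, 4.0), focal_px=100.0, image_size=(200, 200))
    boxes = project_to_views((3.9, 0.0, 1.0), (0.6, 0.6, 1.7), [view])
    if "view0" in boxes:
        x1, y1, x2, y2 = boxes["view0"]
        assert x1 < x2 and y1 < y2 and x2 <= 200


def test_projection_degenerate_geometry_raises():
    view = ViewGeometry(camera=(0.0, 0.0, 1.0), focal_px=100.0, image_size=(200, 200))
    with pytest.raises(ValueError):
        project_to_views((0.0, 0.0, 1.5), (0.2, 0.2, 0.2), [view])
    with pytest.raises(ValueError):
        ViewGeometry(camera=(0, 0, 4), focal_px=0.0, image_size=(200, 200))


# --- splits ----------------------------------------------------------------

def test_splits_largest_remainder_counts():
    cases = [(f"c{i}", "mmor-like") for i in range(10)]
    splits = assign_splits(cases, (0.8, 0.1, 0.1), seed=1)
    from collections import Counter

    counts = Counter(splits.values())
    assert counts == {"train": 8, "val": 1, "test": 1}


def test_splits_partition_and_determinism(small_corpus):
    cases = [(tl.case_id, tl.source_tag) for tl in small_corpus]
    s1 = assign_splits(cases, (0.5, 0.25, 0.25), seed=7)
    s2 = assign_splits(cases, (0.5, 0.25, 0.25), seed=7)
    assert s1 == s2
    assert set(s1) == {c for c, _ in cases}
    assert set(s1.values()) <= {"train", "val", "test"}


def test_splits_fewer_than_three_cases_errors():
    with pytest.raises(ValueError):
        assign_splits([("a", "x"), ("b", "x")], (0.8, 0.1, 0.1), seed=0)


def test_profile_requires_a_visual_modality():
    with pytest.raises(ValueError):
        ModalityProfile(phases=True)  # no visual channel at all


def test_config_invariants():
    with pytest.raises(ValueError):
        SimConfig(n_cases_per_source=0)
    with pytest.raises(ValueError):
        SimConfig(room_extent=(0.0, 6.0, 3.0))
    with pytest.raises(ValueError):
        SimConfig(image_size=(32, 480))
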