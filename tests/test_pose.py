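"""Cutting-pose arithmetic, linkage kinematics, and motion logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import teaprof as tp
from teaprof.pose import Band, MotionDecision, RotationMotion, VerticalMotion


# -- height adjustment d -----------------------------------------------------


@pytest.mark.parametrize(
    "l_near,expect",
    [
        (45.9412, -0.9412),  # nadir-mount field measurement
        (42.6136, 2.3864),
        (35.1825, 9.8175),
        (43.0867, 1.9133),
        (45.0, 0.0),         # ideal pose: l_near = a_near - L
    ],
)
def test_compute_d_reference_values(rig, l_near, expect):
    assert tp.compute_d(rig, l_near) == pytest.approx(expect, abs=1e-9)


@given(st.floats(30, 70), st.floats(-5, 5))
@settings(max_examples=50, deadline=None)
def test_compute_d_is_affine(l_near, delta):
    rig = tp.RigConfig()
    assert tp.compute_d(rig, l_near + delta) == pytest.approx(
        tp.compute_d(rig, l_near) - delta, abs=1e-9
    )


def test_compute_d_rejects_nonpositive(rig):
    with pytest.raises(tp.ParameterError):
        tp.compute_d(rig, 0.0)


# -- angle adjustment alpha --------------------------------------------------


def test_compute_alpha_ideal_and_hand_value(rig):
    assert tp.compute_alpha(rig, rig.a_far - rig.L) == pytest.approx(0.0, abs=1e-12)
    # (10 - (61 - 53.3801)) * 180 / (114 pi) = 2.3801 * 180 / (114 pi)
    expect = 2.3801 * 180.0 / (114.0 * math.pi)
    assert tp.compute_alpha(rig, 53.3801) == pytest.approx(expect, abs=1e-9)
    assert expect == pytest.approx(1.1961, abs=5e-4)


def test_compute_alpha_strictly_increasing(rig):
    values = [tp.compute_alpha(rig, l) for l in np.linspace(40, 70, 20)]
    assert all(b > a for a, b in zip(values, values[1:]))


# -- linkage delta-x ---------------------------------------------------------


def test_delta_x_identity_at_zero_alpha(rig):
    assert tp.compute_delta_x(rig, 0.0) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("b,r,c,alpha", [
    (40.0, 114.0, 80.0, 5.0),
    (40.0, 114.0, 80.0, -5.0),
    (30.0, 100.0, 90.0, 12.5),
    (55.0, 120.0, 110.0, -8.0),
])
def test_delta_x_round_trip_and_root_finding_oracle(b, r, c, alpha):
    rig = tp.RigConfig(b=b, r=r, c_zero=c)
    dx = tp.compute_delta_x(rig, alpha)
    # forward law-of-cosines evaluation recovers alpha
    assert tp.forward_alpha(rig, dx) == pytest.approx(alpha, rel=1e-9, abs=1e-12)
    # independent numeric root-finding on the forward model agrees;
    # bracket clamped to rod lengths the linkage can reach
    x_min = abs(b - r) - c + 1e-6
    x_max = b + r - c - 1e-6
    lo, hi = (0.0, min(dx + 5.0, x_max)) if dx > 0 else (max(dx - 5.0, x_min), 0.0)
    root = brentq(lambda x: tp.forward_alpha(rig, x) - alpha, lo, hi, xtol=1e-12)
    assert dx == pytest.approx(root, abs=1e-8)


def test_delta_x_mechanism_limit(rig):
    theta0 = math.degrees(
        math.acos((rig.b**2 + rig.r**2 - rig.c_zero**2) / (2 * rig.b * rig.r))
    )
    with pytest.raises(tp.MechanismLimitError):
        tp.compute_delta_x(rig, -(theta0 + 0.001))
    with pytest.raises(tp.MechanismLimitError):
        tp.compute_delta_x(rig, 180.0 - theta0 + 0.001)


def test_rig_config_validates_triangle():
    with pytest.raises(tp.ParameterError):
        tp.RigConfig(b=40.0, r=114.0, c_zero=60.0)  # < |b - r|


# -- decision table ----------------------------------------------------------


@pytest.mark.parametrize(
    "l_near,l_far,vertical,rotation",
    [
        (45.0, 53.0, VerticalMotion.HOLD, RotationMotion.HOLD),       # no-op band
        (37.0, 53.0, VerticalMotion.RISE, RotationMotion.ROTATE_DOWN),  # rise + rotate down
        (49.0, 53.0, VerticalMotion.FALL, RotationMotion.ROTATE_UP),
        (45.0, 57.0, VerticalMotion.HOLD, RotationMotion.ROTATE_DOWN),
        (45.0, 48.0, VerticalMotion.HOLD, RotationMotion.ROTATE_UP),
        (500.0, 53.0, VerticalMotion.OUT_OF_RANGE, RotationMotion.HOLD),
        (45.0, 500.0, VerticalMotion.HOLD, RotationMotion.OUT_OF_RANGE),
    ],
)
def test_default_motion_logic(table, l_near, l_far, vertical, rotation):
    decision = tp.decide_motion(table, l_near, l_far)
    assert decision.vertical is vertical
    assert decision.rotation is rotation


def test_table_round_trip_serialization(table, tmp_path):
    path = tmp_path / "table.json"
    import json
    path.write_text(json.dumps(table.to_dict()))
    loaded = tp.DecisionTable.load(path)
    assert loaded.to_dict() == table.to_dict()


@given(
    st.lists(st.floats(30, 70, allow_nan=False), min_size=3, max_size=6, unique=True),
    st.integers(0, 3),
)
@settings(max_examples=40, deadline=None)
def test_table_validation_rejects_gaps_and_overlaps(edges, corruption):
    """Any gapped or overlapping band axis fails validation at load time."""
    edges = sorted(edges)
    bands = [Band(lo, hi) for lo, hi in zip(edges, edges[1:])]
    far = (Band(40.0, 60.0),)
    hold = MotionDecision(VerticalMotion.HOLD, RotationMotion.HOLD)
    grid = {(i, 0): hold for i in range(len(bands))}
    # the clean partition validates
    tp.DecisionTable(near_bands=tuple(bands), far_bands=far, grid=grid)
    if len(bands) < 2:
        return
    bad = list(bands)
    if corruption % 2 == 0:  # open a gap
        b = bad[1]
        bad[1] = Band(b.lo + (b.hi - b.lo) / 2, b.hi)
    else:  # create an overlap
        b = bad[1]
        bad[1] = Band(bad[0].lo + (bad[0].hi - bad[0].lo) / 2, b.hi)
    with pytest.raises(tp.ConfigError):
        tp.DecisionTable(near_bands=tuple(bad), far_bands=far, grid=grid)


def test_incomplete_grid_rejected():
    hold = MotionDecision(VerticalMotion.HOLD, RotationMotion.HOLD)
    with pytest.raises(tp.ConfigError):
        tp.DecisionTable(
            near_bands=(Band(40, 50), Band(50, 60)),
            far_bands=(Band(40, 60),),
            grid={(0, 0): hold},  # missing (1, 0)
        )


# -- pipeline and closed loop ------------------------------------------------


def test_pose_pipeline_reference_row(rig, table):
    pose, decision = tp.pose_pipeline(rig, table, 45.9412, 51.5316)
    assert pose.d == pytest.approx(-0.9412, abs=1e-9)
    assert decision.vertical is VerticalMotion.HOLD
    # forward kinematics on the reported delta_x reproduces alpha
    assert tp.forward_alpha(rig, pose.delta_x) == pytest.approx(pose.alpha, rel=1e-9)


def test_pose_pipeline_fixed_point(rig, table):
    pose, decision = tp.pose_pipeline(rig, table, rig.a_near - rig.L, rig.a_far - rig.L)
    assert pose.d == pytest.approx(0.0, abs=1e-12)
    assert pose.alpha == pytest.approx(0.0, abs=1e-12)
    assert pose.delta_x == pytest.approx(0.0, abs=1e-12)
    assert decision.is_noop and pose.noop


def test_closed_loop_one_step_convergence(rig, table):
    """On a noiseless tilted canopy, one pose update reaches the no-op band."""
    params = tp.SceneParams(
        canopy_arc_peak_depth=44.0, canopy_arc_sag=6.0, tilt=8.0,
        depth_noise_sd=0.0, hole_fraction=0.0, seed=31,
    )
    frame, _ = tp.generate_frame(params, rig)
    mask = tp.segment_shoots(frame.rgb)
    l_near, l_far, _ = tp.extract_l_values(frame, mask)
    cutter = tp.VirtualCutter(rig=rig, l_near=l_near, l_far=l_far)
    pose, first = tp.pose_pipeline(rig, table, cutter.l_near, cutter.l_far)
    assert not first.is_noop
    cutter.apply(pose)
    _, second = tp.pose_pipeline(rig, table, cutter.l_near, cutter.l_far)
    assert second.vertical is VerticalMotion.HOLD
    assert second.rotation is RotationMotion.HOLD
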