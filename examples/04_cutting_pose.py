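"""Compute the cutting pose and motion decision; close the loop once.

d = a_near - l_near - L is the signed height adjustment (positive = raise);
alpha = (L - (a_far - l_far)) * 180/(r*pi) the signed rotation (positive =
left end down); delta_x the stepper travel that produces alpha through the
law-of-cosines linkage. A band table over (l_near, l_far) picks one of ten
motion types.
"""

from teaprof import (
    RigConfig, SceneParams, VirtualCutter, default_decision_table,
    extract_l_values, generate_frame, pose_pipeline, segment_shoots,
)

rig = RigConfig()  # a_near=55, a_far=61, L=10, r=114 cm
table = default_decision_table()

# a tilted canopy: left side rises toward the camera
params = SceneParams(canopy_arc_peak_depth=44.0, tilt=8.0,
                     depth_noise_sd=0.0, hole_fraction=0.0, seed=31)
frame, _ = generate_frame(params, rig)
mask = segment_shoots(frame.rgb)
l_near, l_far, _ = extract_l_values(frame, mask)
print(f"measured l_near={l_near:.3f} cm, l_far={l_far:.3f} cm")

pose, decision = pose_pipeline(rig, table, l_near, l_far)
print(f"pose: d={pose.d:+.4f} cm, alpha={pose.alpha:+.4f} deg, delta_x={pose.delta_x:+.4f} cm")
print(f"decision: vertical={decision.vertical.value}, rotation={decision.rotation.value}")

cutter = VirtualCutter(rig=rig, l_near=l_near, l_far=l_far)
cutter.apply(pose)
_, second = pose_pipeline(rig, table, cutter.l_near, cutter.l_far)
print(
    f"after applying the pose: l_near={cutter.l_near:.3f}, l_far={cutter.l_far:.3f} "
    f"-> decision ({second.vertical.value}, {second.rotation.value})"
)
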