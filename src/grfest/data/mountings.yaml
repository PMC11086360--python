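# IMU mounting table: one sensor per segment (12 sensors).  lever is the
# position of the sensor origin in the segment frame, measured from the
# segment's proximal joint; entries are [x, y, z] with each component either a
# number in metres or a string "<frac>*L" meaning a fraction of the segment
# length.  mount_rotation is a scalar-first quaternion sensor->segment
# (identity: sensor axes aligned with the segment frame).
#
# Placements mirror typical strap-on sites: sacrum (pelvis), upper thoracic
# spine (trunk), distal-quarter upper arm, mid forearm, distal-quarter thigh,
# distal shank at the malleoli, and mid-dorsum of the foot.

mountings:
  pelvis:     {lever: [0.0, 0.08, 0.05],          mount_rotation: [1, 0, 0, 0]}
  trunk:      {lever: [0.0, 0.06, "0.85*L"],      mount_rotation: [1, 0, 0, 0]}
  upper_arm_l: {lever: [0.04, 0.0, "-0.75*L"],    mount_rotation: [1, 0, 0, 0]}
  upper_arm_r: {lever: [-0.04, 0.0, "-0.75*L"],   mount_rotation: [1, 0, 0, 0]}
  forearm_l:  {lever: [0.03, 0.0, "-0.50*L"],     mount_rotation: [1, 0, 0, 0]}
  forearm_r:  {lever: [-0.03, 0.0, "-0.50*L"],    mount_rotation: [1, 0, 0, 0]}
  thigh_l:    {lever: [0.05, 0.0, "-0.75*L"],     mount_rotation: [1, 0, 0, 0]}
  thigh_r:    {lever: [-0.05, 0.0, "-0.75*L"],    mount_rotation: [1, 0, 0, 0]}
  shank_l:    {lever: [0.0, -0.03, "-0.90*L"],    mount_rotation: [1, 0, 0, 0]}
  shank_r:    {lever: [0.0, -0.03, "-0.90*L"],    mount_rotation: [1, 0, 0, 0]}
  foot_l:     {lever: [0.0, -0.06, -0.03],        mount_rotation: [1, 0, 0, 0]}
  foot_r:     {lever: [0.0, -0.06, -0.03],        mount_rotation: [1, 0, 0, 0]}
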