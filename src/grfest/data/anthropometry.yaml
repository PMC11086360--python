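# Default anthropometry table: per-segment mass fraction (of body mass),
# length fraction (of body height), COM position fraction (of segment length,
# measured from the proximal joint along the segment axis), and radius-of-
# gyration fractions (of segment length, about the segment-frame X/Y/Z axes
# through the COM).
#
# Values are adapted from published adult-male segment inertia data (adjusted
# Zatsiorsky-style fractions) collapsed onto the 12-link layout used here: the
# head is folded into the trunk segment and the hand into the forearm.  Mass
# fractions are renormalized to sum to exactly 1 at model-build time.
#
# axis: direction of the segment's long axis in its own frame
#   ("+z" = from proximal joint toward distal tip upward, "-z" = downward).
# The foot segment is handled by the foot-geometry table (its long axis is
# horizontal); its entry here supplies mass and gyration fractions only.

segments:
  pelvis:
    mass_frac: 0.1117
    length_frac: 0.078      # hip-joint line to lumbar joint
    com_frac: 0.45
    axis: "+z"
    gyration: [0.95, 0.95, 1.05]   # wide, squat segment
  trunk:                     # thorax + abdomen + head + neck
    mass_frac: 0.3923
    length_frac: 0.300      # lumbar joint to shoulder line
    com_frac: 0.58
    axis: "+z"
    gyration: [0.48, 0.45, 0.25]
  upper_arm:
    mass_frac: 0.0271
    length_frac: 0.172
    com_frac: 0.577
    axis: "-z"
    gyration: [0.285, 0.269, 0.158]
  forearm:                   # forearm + hand
    mass_frac: 0.0223
    length_frac: 0.157
    com_frac: 0.57
    axis: "-z"
    gyration: [0.30, 0.29, 0.13]
  thigh:
    mass_frac: 0.1416
    length_frac: 0.245
    com_frac: 0.41
    axis: "-z"
    gyration: [0.329, 0.329, 0.149]
  shank:
    mass_frac: 0.0433
    length_frac: 0.246
    com_frac: 0.44
    axis: "-z"
    gyration: [0.251, 0.246, 0.102]
  foot:
    mass_frac: 0.0137
    length_frac: 0.152      # heel to toe tip; vertical placement from foot geometry
    com_frac: 0.40          # along the sole axis, from the heel
    axis: "foot"
    gyration: [0.257, 0.124, 0.245]

# Frame-placement fractions of body height used when assembling the chain.
frame:
  hip_half_width_frac: 0.053     # pelvis origin (hip-joint midpoint) to each hip
  shoulder_half_width_frac: 0.110
  ankle_height_frac: 0.039       # ankle joint above the sole plane
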