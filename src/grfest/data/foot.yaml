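# Foot-ground contact geometry.  Distances are fractions of total foot length
# (heel to toe tip) unless suffixed _frac_height; the foot frame origin is the
# ankle joint, anterior is -Y, lateral is +/-X, up is +Z.
#
# The 22 contact points per foot are laid out as 11 rows of 2 points spanning
# heel to toe tip; row half-width follows a piecewise-linear profile through
# the heel width, the metatarsophalangeal (MTP) width, and the width between
# the first and second proximal phalanges at the toe.  Rows at or behind the
# MTP line sit on the sole plane (ankle height below the ankle); rows forward
# of it sit at the first-proximal-phalanx height.

foot_geometry:
  heel_dist_frac: 0.25        # ankle to heel, posterior
  mtp_dist_frac: 0.55         # ankle to MTP line, anterior
  toe_dist_frac: 0.75         # ankle to tip of second proximal phalanx, anterior
  heel_width_frac: 0.24
  mtp_width_frac: 0.36
  toe_width_frac: 0.14
  ankle_height_frac_height: 0.039    # fraction of body height
  phalanx_height_frac_height: 0.018  # first proximal phalanx height, fraction of body height
  n_rows: 11
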