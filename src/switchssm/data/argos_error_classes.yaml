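# Default Argos location-quality class error table used by switchssm.
#
# These are SYNTHETIC package defaults: plausible per-class t-distribution
# scale (tau, km, per axis: x = longitude direction, y = latitude direction)
# and degrees-of-freedom (nu) values with the magnitudes and orderings
# typical of published Argos/SRDL error analyses (scales grow and tails
# thicken from class 3 down to class B).  They are NOT a published
# calibration; supply your own table for real-data work.
#
# Simulation and inference machinery only requires tau > 0 and nu > 0 per
# class; nothing in the package depends on these particular numbers.
classes:
  "3": {tau_x: 0.29, tau_y: 0.22, nu: 4.0}
  "2": {tau_x: 0.55, tau_y: 0.41, nu: 3.5}
  "1": {tau_x: 1.10, tau_y: 0.79, nu: 3.0}
  "0": {tau_x: 3.18, tau_y: 2.16, nu: 2.1}
  "A": {tau_x: 1.80, tau_y: 1.40, nu: 2.3}
  "B": {tau_x: 4.20, tau_y: 3.00, nu: 2.0}
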