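# Species registry: timing of cortical neurogenesis, deeper-layer targets,
# adult neuron counts and progenitor cell-cycle measurements.
#
# Times are embryonic days (continuous axis); cell-cycle lengths are hours.
# phi is the fraction of final cortical neurons residing in the deeper
# (infragranular, V/VI) layers. For macaque and human no direct supragranular
# percentage is available for all layers; phi = 0.29 is taken as
# 1 - 0.71 from the capuchin-monkey supragranular fraction and used as a
# primate proxy (human values additionally borrow the macaque cell cycle).
mouse:
  t0: 11.0
  tF: 19.0
  tM: 17.0
  phi: 0.52
  N_adult: 13.69e+6
  P0_literature: 375000.0
  cell_cycle:
    constant_hours: 14.3
    anchors: [[12.0, 10.2], [16.0, 18.4]]
  # reference division strategies (alpha0, alphaS, betaF, tS) per cycle model
  strategies:
    constant:
      - {tc_scale: 1.0, strategy: [0.4, 0.5, 0.7, 14.0]}
    age_dependent:
      - {tc_scale: 1.0, strategy: [0.2, 0.7, 1.0, 16.0]}
macaque:
  t0: 40.0
  tF: 100.0
  tM: 64.0
  phi: 0.29
  N_adult: 1.71e+9
  P0_literature: null
  cell_cycle:
    constant_hours: 34.67
    anchors: [[40.0, 23.0], [60.0, 54.0], [80.0, 27.0]]
  strategies:
    constant:
      - {tc_scale: 1.0, strategy: [0.1, 1.0, 0.7, 65.5]}
    age_dependent:
      - {tc_scale: 1.0, strategy: [0.5, 0.8, 1.0, 63.5]}
human:
  t0: 40.0
  tF: 117.0
  tM: 93.0
  phi: 0.29
  N_adult: 16.34e+9
  P0_literature: null
  # no in-vivo human progenitor cell-cycle data; macaque used as proxy
  cell_cycle:
    constant_hours: 34.67
    anchors: [[40.0, 23.0], [60.0, 54.0], [80.0, 27.0]]
  # age-dependent entries at tc_scale 1.5 / 2.0 cover hypothetical uniformly
  # longer human cell cycles
  strategies:
    constant:
      - {tc_scale: 1.0, strategy: [0.3, 1.0, 0.5, 94.0]}
    age_dependent:
      - {tc_scale: 1.0, strategy: [0.1, 0.9, 0.8, 92.0]}
      - {tc_scale: 1.5, strategy: [0.4, 0.8, 0.7, 84.5]}
      - {tc_scale: 2.0, strategy: [0.1, 0.4, 0.7, 56.0]}
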