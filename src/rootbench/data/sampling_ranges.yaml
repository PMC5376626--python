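# Parameter sampling intervals for the random root-system library.
#
# Each entry maps a simulation parameter to a [low, high] interval; a library
# draw samples uniformly within it (integer-uniform for n_axes).  The
# intervals were fixed once, chosen so that the morphology of a large
# generated library stays inside realistic envelopes for juvenile
# rhizotron-grown plants (axis diameters of a few tenths of a millimetre,
# depths of tens to a few hundred millimetres, up to a few thousand
# laterals), while keeping individual systems small enough to rasterize and
# analyze in bulk.
version: 1
fibrous:
  n_axes: [3, 12]
  duration_days: [12, 35]
  elong_coeff: [3.0, 9.0]          # mm per day per mm of apical diameter
  d_axis_mm: [0.25, 0.42]
  d_min_mm: [0.10, 0.16]
  diam_ratio: [0.25, 0.40]
  diam_cv: [0.10, 0.25]
  interbranch_mm: [2.0, 5.0]
  insertion_angle_mean_deg: [45.0, 80.0]
  insertion_angle_sd_deg: [5.0, 15.0]
  tropism_strength: [0.05, 0.30]
  direction_noise_sd_deg: [5.0, 20.0]
  sec_growth_coeff: [0.0, 0.0]     # no secondary growth in fibrous systems
tap:
  n_axes: [1, 1]
  duration_days: [15, 40]
  elong_coeff: [6.0, 12.0]
  d_axis_mm: [0.40, 0.80]
  d_min_mm: [0.10, 0.16]
  diam_ratio: [0.25, 0.40]
  diam_cv: [0.10, 0.25]
  interbranch_mm: [2.0, 5.0]
  insertion_angle_mean_deg: [45.0, 80.0]
  insertion_angle_sd_deg: [5.0, 15.0]
  tropism_strength: [0.10, 0.40]
  direction_noise_sd_deg: [3.0, 15.0]
  sec_growth_coeff: [2.0e-05, 2.5e-04]  # mm per apex per day of radial thickening
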