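# Synthetic default parameters for the NT mixture model and the screening
# pipeline.  These are NOT estimates from any real screening programme: they
# are a realistic synthetic parameter set (median NT rising from 1.20 mm at
# CRL 45 mm to 1.90 mm at CRL 84 mm, an elevated CRL-independent component,
# and an affected distribution centred near 2.75 mm) used as the generative
# truth for simulated cohorts and as the fixture configuration for tests.
mixture:
  unaffected:
    dependent:            # log10(NT) ~ N(a + b*crl + c*crl^2, sigma^2)
      a: -0.3952520
      b: 0.0134496
      c: -0.0000645919
      sigma: 0.085
    independent:          # NT (mm) ~ N(mu, sigma^2), truncated at zero
      mu: 2.0
      sigma: 0.6
    proportion:           # CRL-independent mixing fraction anchors
      p45: 0.12
      p84: 0.03
      form: linear
  affected:
    independent:
      mu: 2.75
      sigma: 0.95
    prop_independent: 0.94
truncation:               # clamp observed NT before likelihood ratios
  lower: 0.6
  upper: 6.0
  scale: mm
weeks:
  anchors: {11: 49.0, 12: 62.0, 13: 76.0}
  boundaries: [45.0, 55.0, 69.0, 84.0]
cohort:
  n_affected: 104
  n_unaffected: 22284
evaluation:
  fpr_targets: [0.01, 0.03, 0.05, 0.10]
  dr_targets: [0.50, 0.60, 0.70, 0.80, 0.90]
# Maternal-age-specific prior risk of a Down's syndrome pregnancy.  This is
# a stand-in lookup table in the style of published age-risk regressions
# (baseline-plus-exponential in age); the pipeline's comparisons do not
# depend on the specific curve.
age_risk:
  kind: table
  table:
    - [15, 0.000633462]
    - [16, 0.000635602]
    - [17, 0.00063845]
    - [18, 0.000642241]
    - [19, 0.000647288]
    - [20, 0.000654005]
    - [21, 0.000662946]
    - [22, 0.000674847]
    - [23, 0.000690689]
    - [24, 0.000711776]
    - [25, 0.000739844]
    - [26, 0.000777206]
    - [27, 0.000826939]
    - [28, 0.000893137]
    - [29, 0.000981253]
    - [30, 0.00109854]
    - [31, 0.00125467]
    - [32, 0.00146248]
    - [33, 0.00173911]
    - [34, 0.00210732]
    - [35, 0.00259744]
    - [36, 0.00324983]
    - [37, 0.00411823]
    - [38, 0.00527416]
    - [39, 0.00681279]
    - [40, 0.00886086]
    - [41, 0.011587]
    - [42, 0.0152158]
    - [43, 0.0200461]
    - [44, 0.0264756]
    - [45, 0.0350338]
    - [46, 0.0464257]
    - [47, 0.0615893]
    - [48, 0.0817734]
    - [49, 0.10864]
    - [50, 0.144403]
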