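# FSAm-NPS component threshold tables (2017 FSA/HCSP publication), per basis.
#
# A component's points are the number of thresholds strictly below the
# value ("value > threshold" moves to the next band; boundary values take
# the lower band). Where a component does not award one point per band
# (FV%), an explicit `points` list gives the value for 0, 1, 2, ... bands
# exceeded.
#
# Negative components (energy kJ, sugars g, SFA g, sodium mg): 0-10 points.
# Positive components (protein g, fiber g, FV %): 0-5 points.
# FV points for beverages are capped at 5 so that every score stays inside
# the -15..+40 scale of the plain subtraction rule.

mode: paper_subtraction

solid:
  energy_kj:
    thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
  sugars_g:
    thresholds: [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
  sfa_g:
    thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sodium_mg:
    thresholds: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
  protein_g:
    thresholds: [1.6, 3.2, 4.8, 6.4, 8.0]
  fiber_g:
    thresholds: [0.9, 1.9, 2.8, 3.7, 4.7]
  fv_percent:
    thresholds: [40, 60, 80]
    points: [0, 1, 2, 5]

beverage:
  energy_kj:
    thresholds: [0, 30, 60, 90, 120, 150, 180, 210, 240, 270]
  sugars_g:
    thresholds: [0, 1.5, 3, 4.5, 6, 7.5, 9, 10.5, 12, 13.5]
  sfa_g:
    thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sodium_mg:
    thresholds: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
  protein_g:
    thresholds: [1.6, 3.2, 4.8, 6.4, 8.0]
  fiber_g:
    thresholds: [0.9, 1.9, 2.8, 3.7, 4.7]
  fv_percent:
    thresholds: [40, 60, 80]
    points: [0, 2, 4, 5]
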