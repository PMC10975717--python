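# Nutri-Score component point tables for general foods (per 100 g),
# as used for processed meat products.
#
# Each row means: a value STRICTLY GREATER than `above` earns `points`;
# values at or below the first bound earn 0 points (boundary values take
# the lower score).  Bounds must be strictly increasing and points
# non-decreasing.  The FVL (fruits/vegetables/pulses/nuts/permitted oils)
# table has no 3- or 4-point rows: attainable points are {0, 1, 2, 5}.
#
# `protein_white` applies to all meat under the original algorithm and to
# white meat under the refined algorithm; `protein_red` is the refined
# algorithm's 2-point cap for red meat and its products.
version: 1
tables:
  energy:
    unit: kJ/100 g
    max_points: 10
    thresholds:
      - {above: 335, points: 1}
      - {above: 670, points: 2}
      - {above: 1005, points: 3}
      - {above: 1340, points: 4}
      - {above: 1675, points: 5}
      - {above: 2010, points: 6}
      - {above: 2345, points: 7}
      - {above: 2680, points: 8}
      - {above: 3015, points: 9}
      - {above: 3350, points: 10}
  sugars:
    unit: g/100 g
    max_points: 10
    thresholds:
      - {above: 4.5, points: 1}
      - {above: 9, points: 2}
      - {above: 13.5, points: 3}
      - {above: 18, points: 4}
      - {above: 22.5, points: 5}
      - {above: 27, points: 6}
      - {above: 31, points: 7}
      - {above: 36, points: 8}
      - {above: 40, points: 9}
      - {above: 45, points: 10}
  sfa:
    unit: g/100 g
    max_points: 10
    thresholds:
      - {above: 1, points: 1}
      - {above: 2, points: 2}
      - {above: 3, points: 3}
      - {above: 4, points: 4}
      - {above: 5, points: 5}
      - {above: 6, points: 6}
      - {above: 7, points: 7}
      - {above: 8, points: 8}
      - {above: 9, points: 9}
      - {above: 10, points: 10}
  sodium:
    unit: mg/100 g
    max_points: 10
    thresholds:
      - {above: 90, points: 1}
      - {above: 180, points: 2}
      - {above: 270, points: 3}
      - {above: 360, points: 4}
      - {above: 450, points: 5}
      - {above: 540, points: 6}
      - {above: 630, points: 7}
      - {above: 720, points: 8}
      - {above: 810, points: 9}
      - {above: 900, points: 10}
  fvl:
    unit: "%"
    max_points: 5
    thresholds:
      - {above: 40, points: 1}
      - {above: 60, points: 2}
      - {above: 80, points: 5}
  fibre:
    unit: g/100 g
    max_points: 5
    thresholds:
      - {above: 0.9, points: 1}
      - {above: 1.9, points: 2}
      - {above: 2.8, points: 3}
      - {above: 3.7, points: 4}
      - {above: 4.7, points: 5}
  protein_white:
    unit: g/100 g
    max_points: 5
    thresholds:
      - {above: 1.6, points: 1}
      - {above: 3.2, points: 2}
      - {above: 4.8, points: 3}
      - {above: 6.4, points: 4}
      - {above: 8.0, points: 5}
  protein_red:
    unit: g/100 g
    max_points: 2
    thresholds:
      - {above: 2.4, points: 1}
      - {above: 4.8, points: 2}
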