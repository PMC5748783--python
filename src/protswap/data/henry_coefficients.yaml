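# Henry (2005) predictive BMR equations, adult bands, MJ/day.
# weight_only:   BMR = w * weight_kg + c
# weight_height: BMR = w * weight_kg + h * height_m + c
# Bands are [age_min, age_max); the last band includes its upper edge.
mj_to_kcal: 239.005736
weight_only:
  male:
    - {age_min: 18, age_max: 30, w: 0.0669, c: 2.28}
    - {age_min: 30, age_max: 60, w: 0.0592, c: 2.48}
    - {age_min: 60, age_max: 70, w: 0.0543, c: 2.37}
  female:
    - {age_min: 18, age_max: 30, w: 0.0546, c: 2.33}
    - {age_min: 30, age_max: 60, w: 0.0407, c: 2.90}
    - {age_min: 60, age_max: 70, w: 0.0429, c: 2.39}
weight_height:
  male:
    - {age_min: 18, age_max: 30, w: 0.0600, h: 1.31, c: 0.473}
    - {age_min: 30, age_max: 60, w: 0.0476, h: 2.26, c: -0.574}
    - {age_min: 60, age_max: 70, w: 0.0478, h: 2.26, c: -1.070}
  female:
    - {age_min: 18, age_max: 30, w: 0.0433, h: 2.57, c: -1.180}
    - {age_min: 30, age_max: 60, w: 0.0342, h: 2.10, c: -0.0486}
    - {age_min: 60, age_max: 70, w: 0.0356, h: 1.76, c: 0.0448}
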