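# Default coding schemes (editable copy of the package defaults).
# Pass an edited copy via `load_scheme(path)` or the CLI --config scheme_path.

micronutrients:
  # three-tier nutrients: [substandard below, standard at-or-above];
  # between the bounds codes suboptimal (1)
  vitamin_b12: [211.0, 350.0]     # pg/ml
  vitamin_d: [20.0, 30.0]         # ng/ml
  folic_acid: [3.15, 6.8]         # ng/ml
  ferritin_thresholds:            # binary 0/2, sex- and age-dependent [ng/ml]
    male/under_18: 14.0
    male/adult: 20.0
    female/under_18: 13.0
    female/adult: 10.0

expertise:
  # [lower bound in years, code], top-down; shared boundaries take the
  # higher code; the top senior bracket is strictly > years_senior_top
  years_highest_brackets: [[8.0, 4], [5.0, 3], [3.0, 2], [0.0, 1]]
  years_senior_brackets: [[7.0, 3], [3.0, 2], [0.0, 1]]
  years_senior_top: 10.0
  elite_threshold: 13

polygenic:
  # per-SNP effect-allele weights by sex (unit weights by default)
  male: {rs699: 1.0, rs6942022: 1.0, rs1544410: 1.0}
  female: {rs1815739: 1.0, rs699: 1.0, rs7247312: 1.0, rs1801394: 1.0,
           rs660339: 1.0}

sport_components:
  # speed component (tapping Hz / 10 m sprint s) + power component (cm or RSI)
  basketball_3x3: [tapping, cmj_height]
  volleyball: [tapping, cmj_height]
  artistic_gymnastics: [tapping, cmj_height]
  trampoline_gymnastics: [tapping, cmj_height]
  rhythmic_gymnastics: [tapping, drop_jump_rsi]
  table_tennis: [tapping, drop_jump_rsi]
  ice_hockey: [sprint_10m, cmj_height]
  modern_pentathlon: [tapping, sergeant_height]

# PSS-4 positively worded items reverse-coded before averaging ([] disables)
pss4_reverse_items: [2, 3]
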