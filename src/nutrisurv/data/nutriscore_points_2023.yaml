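# Point tables for the updated (2023) Nutri-Score nutrient profiling model.
#
# Transcribed from the 2023 algorithm update adopted by the European
# Nutri-Score governance (Scientific Committee reports: main algorithm
# update 2022, beverages update 2023).
#
# Semantics: a value STRICTLY GREATER than the k-th threshold earns the
# points of the k-th bin; a value equal to a threshold earns the lower bin.
# Where a `points` list is absent, bin k earns k points (contiguous from 0).
# Where present, `points[k-1]` is the points earned above threshold k
# (below the first threshold always earns 0).
#
# Units: energy kJ/100 g (or /100 mL); sugars, saturated fat, salt, fibre,
# protein g/100 g (or /100 mL); fvl = % fruits, vegetables and legumes;
# satfat_ratio = 100 * saturated fat / total fat.
# For fats/oils/nuts/seeds the energy component value is the energy from
# saturates (37 kJ per g of saturated fat), scored against the same kJ
# thresholds.
version: 2023
constants:
  kj_per_kcal: 4.184
  salt_g_per_sodium_g: 2.5
rules:
  # protein points are not counted when unfavourable points reach this
  # cutoff, except for cheeses (always counted) and red meat products
  # (counted but capped below)
  protein_suppression_min_a_points: 11
  red_meat_protein_cap: 2
components:
  general:
    unfavourable:
      energy:
        thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
      sugars:
        thresholds: [3.4, 6.8, 10, 14, 17, 20, 24, 27, 31, 34, 37, 41, 44, 48, 51]
      saturated_fat:
        thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt:
        thresholds: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                     2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
    favourable:
      protein:
        thresholds: [2.4, 4.8, 7.2, 9.6, 12, 14, 17]
      fibre:
        thresholds: [3.0, 4.1, 5.2, 6.3, 7.4]
      fvl:
        thresholds: [40, 60, 80]
        points: [1, 2, 5]
  fats_oils_nuts_seeds:
    unfavourable:
      energy:
        thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
      sugars:
        thresholds: [3.4, 6.8, 10, 14, 17, 20, 24, 27, 31, 34, 37, 41, 44, 48, 51]
      satfat_ratio:
        thresholds: [10, 16, 22, 28, 34, 40, 46, 52, 58, 64]
      salt:
        thresholds: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                     2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
    favourable:
      protein:
        thresholds: [2.4, 4.8, 7.2, 9.6, 12, 14, 17]
      fibre:
        thresholds: [3.0, 4.1, 5.2, 6.3, 7.4]
      fvl:
        thresholds: [40, 60, 80]
        points: [1, 2, 5]
  beverage:
    unfavourable:
      energy:
        thresholds: [30, 90, 150, 210, 240, 270, 300, 330, 360, 390]
      sugars:
        thresholds: [0.5, 2, 3.5, 5, 6, 7, 8, 9, 10, 11]
      saturated_fat:
        thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt:
        thresholds: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                     2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
    favourable:
      protein:
        thresholds: [1.2, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0]
      fibre:
        thresholds: [3.0, 4.1, 5.2, 6.3, 7.4]
      fvl:
        thresholds: [40, 60, 80]
        points: [2, 4, 6]
# Letter bands: list of [letter, inclusive upper score bound]; the last
# band is open-ended. Water is assigned A directly and never enters here;
# non-water beverages therefore span B..E.
bands:
  food:
    - [A, 0]
    - [B, 2]
    - [C, 10]
    - [D, 18]
    - [E, null]
  fats_oils_nuts_seeds:
    - [A, -6]
    - [B, 2]
    - [C, 10]
    - [D, 18]
    - [E, null]
  beverage:
    - [B, 2]
    - [C, 6]
    - [D, 9]
    - [E, null]
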