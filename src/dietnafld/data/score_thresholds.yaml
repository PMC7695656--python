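# Guideline thresholds for the a priori diet quality scores.
# Quantities are g/day unless stated; weekly criteria are applied to
# daily intake * 7. Editing this file swaps guideline editions without
# code changes.
ddg:
  vegetables_min_g_day: 200
  fruit_min_g_day: 200
  whole_grains_min_g_day: 90
  legumes_min_g_week: 135
  nuts_min_g_day: 15
  fish_min_g_week: 100
  dairy_min_g_day: 350
  tea_min_ml_day: 150
  whole_grain_ratio_min: 0.5        # whole grains / all grains
  unsaturated_fat_ratio_min: 0.5    # (MUFA+PUFA) / total fat
  red_processed_meat_max_g_week: 300   # strict <
  sugary_drinks_max_ml_day: 150        # <=
  alcohol_max_g_day: 10                # <=
  salt_max_g_day: 6                    # <=
who:
  veg_fruit_min_g_day: 400          # >=
  sugar_max_g_day: 10               # strict <, added sugar
  fat_energy_pct_max: 30            # strict <
  sfa_energy_pct_max: 10            # strict <
  trans_energy_pct_max: 1           # strict <
  salt_max_g_day: 5                 # strict <
salt_from_sodium_factor: 2.54       # g salt per g sodium
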