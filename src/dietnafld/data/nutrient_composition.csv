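food_group,energy_kcal,total_fat_g,sfa_g,mufa_g,pufa_g,trans_fat_g,animal_protein_g,vegetable_protein_g,fibre_g,mono_disaccharides_g,added_sugar_g,alcohol_g,sodium_g,potassium_mg,haem_iron_mg,vitamin_e_mg
fruit,0.5,0.002,0,0.001,0.001,0,0,0.005,0.02,0.10,0,0,0.0001,2.0,0,0.002
fruit_juice,0.45,0,0,0,0,0,0,0.002,0.002,0.10,0.02,0,0.0001,1.5,0,0.001
nuts,6.0,0.55,0.08,0.30,0.15,0,0,0.20,0.08,0.04,0,0,0.002,6.0,0,0.25
vegetable_oils_and_stanols,8.0,1.0,0.15,0.45,0.35,0.002,0,0,0,0,0,0,0,0,0,0.5
margarine_or_butter,7.0,0.80,0.30,0.35,0.15,0.010,0.002,0,0,0.005,0,0,0.002,0.3,0,0.10
tomatoes,0.18,0.002,0,0.001,0.001,0,0,0.010,0.012,0.025,0,0,0.0001,2.4,0,0.005
vegetables,0.25,0.003,0.001,0.001,0.001,0,0,0.020,0.025,0.02,0,0,0.0002,3.0,0,0.005
potatoes,0.8,0.001,0,0,0,0,0,0.020,0.020,0.008,0,0,0.0001,4.0,0,0.001
legumes,1.0,0.005,0.001,0.002,0.002,0,0,0.080,0.070,0.015,0,0,0.0005,3.0,0,0.002
whole_grains,2.4,0.020,0.004,0.005,0.008,0,0,0.100,0.090,0.015,0.005,0,0.005,2.5,0,0.010
refined_grains,2.6,0.010,0.004,0.003,0.003,0,0,0.080,0.030,0.020,0.010,0,0.005,1.2,0,0.003
egg_products,1.5,0.100,0.030,0.040,0.015,0,0.120,0,0,0.005,0,0,0.0013,1.3,0.001,0.010
red_meat,2.0,0.150,0.060,0.060,0.010,0.002,0.200,0,0,0,0,0,0.002,3.0,0.010,0.004
refined_or_organ_meat,2.5,0.250,0.100,0.100,0.020,0.002,0.150,0,0,0.005,0,0,0.020,2.5,0.008,0.002
poultry,1.5,0.080,0.025,0.030,0.015,0,0.200,0,0,0,0,0,0.001,3.0,0.004,0.003
fish,1.5,0.080,0.020,0.030,0.025,0,0.180,0,0,0,0,0,0.002,3.0,0.003,0.010
low_fat_dairy,0.45,0.015,0.010,0.004,0.001,0,0.035,0,0,0.045,0.01,0,0.0005,1.5,0,0.001
high_fat_dairy,1.0,0.080,0.050,0.020,0.004,0.003,0.030,0,0,0.040,0.01,0,0.007,1.0,0,0.002
salty_snacks,5.0,0.300,0.120,0.120,0.050,0.005,0.005,0.050,0.030,0.02,0.01,0,0.012,3.5,0,0.030
sauces,3.0,0.250,0.040,0.100,0.100,0,0.005,0.010,0.005,0.05,0.05,0,0.030,1.0,0,0.050
sweet_snacks_or_desserts,4.0,0.200,0.100,0.070,0.030,0.005,0.010,0.030,0.015,0.35,0.25,0,0.002,1.5,0,0.015
sugary_drinks,0.4,0,0,0,0,0,0,0,0,0.10,0.10,0,0.0001,0.2,0,0
diet_soda_or_water,0.0,0,0,0,0,0,0,0,0,0,0,0,0.0001,0.1,0,0
tea,0.01,0,0,0,0,0,0,0,0,0,0,0,0,0.2,0,0
coffee,0.01,0,0,0,0,0,0,0.001,0,0,0,0,0.0001,0.5,0,0
wine,0.8,0,0,0,0,0,0,0,0,0.005,0,0.100,0.0001,1.0,0,0
beer_or_spirits,0.4,0,0,0,0,0,0,0.003,0,0.003,0,0.040,0.0001,0.4,0,0
soy_products,0.8,0.020,0.003,0.005,0.010,0,0,0.080,0.010,0.010,0,0,0.001,1.5,0,0.010
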