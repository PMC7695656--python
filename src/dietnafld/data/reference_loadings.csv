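food_group,median,p25,p75,vegetable_and_fish,red_meat_and_alcohol,traditional,salty_snacks_and_sauces,high_fat_dairy_and_refined_grains
fruit,301,132,529,0.292,-0.225,0,0,0.144
fruit_juice,21,0,107,-0.105,0,0,0,0.257
nuts,0.7,0.0,4.5,0.110,-0.116,0,0.265,0
vegetable_oils_and_stanols,27,14,43,0.182,0,0.543,0,0
margarine_or_butter,11,6,19,0.109,0,0.391,0,0.185
tomatoes,18,5,35,0.586,-0.111,0,0.143,0
vegetables,211,131,325,0.584,0,0.168,0,0
potatoes,68,35,102,0,0.112,0.314,0,0
legumes,9,0,30,0.142,0,0,0.236,0
whole_grains,105,68,143,0,0,0.396,0,-0.196
refined_grains,30,14,56,0,0.169,0.167,0,0.346
egg_products,13,7,21,0.110,0,0.229,0,0
red_meat,41,23,61,0.196,0.599,0.223,0,0.174
refined_or_organ_meat,24,13,38,0.177,0.546,0.214,0,0.167
poultry,9,4,15,0.308,0,0,0.185,0
fish,22,10,38,0.358,0,0,0.141,0
low_fat_dairy,193,96,319,0.147,0,0.183,0,-0.270
high_fat_dairy,20,7,46,0,0.114,0,0,0.401
salty_snacks,22,10,40,0,0.246,0,0.622,0
sauces,2.7,0.6,6.3,0.267,0,0.118,0.480,0.158
sweet_snacks_or_desserts,79,48,121,0,0,0.439,0.181,0.246
sugary_drinks,0,0,43,0,0.164,0,0.137,0.178
diet_soda_or_water,13,0,150,0.191,-0.149,0,0.123,0
tea,174,54,406,0.138,-0.308,0.179,0,0
coffee,406,174,406,0,0.212,0,0,0
wine,21,0,83,0,0.186,0,0,0
beer_or_spirits,0,0,27,-0.105,0.248,0,0,0
soy_products,0,0,0,0,-0.157,0,0.129,0
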