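allergen,scheme,dose_mg,note
Milk,VITAL3,0.2,
Milk,Germany,0.1,Based on VITAL 2.0 action levels
Milk,Netherlands,0.016,
Milk,Belgium,2,
Milk,FAO-WHO,2.0,
Egg,VITAL3,0.2,
Egg,Germany,0.03,Based on VITAL 2.0 action levels
Egg,Netherlands,0.0043,
Egg,Belgium,2,
Egg,FAO-WHO,2.0,
Peanut,VITAL3,0.2,
Peanut,Germany,0.2,Based on VITAL 2.0 action levels
Peanut,Netherlands,0.015,
Peanut,Belgium,2,
Peanut,FAO-WHO,2.0,
Soybean,VITAL3,0.5,
Soybean,Germany,1,Based on VITAL 2.0 action levels
Soybean,Netherlands,0.078,
Soybean,Belgium,5,
Soybean,FAO-WHO,nd,
Hazelnut,VITAL3,0.1,
Hazelnut,Germany,0.1,Based on VITAL 2.0 action levels
Hazelnut,Netherlands,0.011,
Hazelnut,Belgium,3,
Hazelnut,FAO-WHO,3.0,
Almond,VITAL3,0.1,
Almond,Germany,nd,
Almond,Netherlands,nd,
Almond,Belgium,1,
Almond,FAO-WHO,1.0,Provisional value
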