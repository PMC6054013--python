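class,cultivated_yield,maturity,agb_density
peat_forest,0.0,0,550.0
mineral_forest,0.0,0,650.0
agroforest,0.6,2,300.0
timber_plantation,3.0,5,200.0
oil_palm_plantation,12.0,3,130.0
agriculture,2.5,1,20.0
settlement,0.0,0,10.0
degraded_land,0.0,0,40.0
__peat__,3000.0,0,60.0
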