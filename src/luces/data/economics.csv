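commodity,farm_gate_price,production_cost,yield_per_ha
rattan,1800.0,30.0,0.3
jelutong,2600.0,30.0,0.2
timber,260.0,60.0,2.0
community_timber,260.0,60.0,2.0
rubber,900.0,40.0,0.6
rice,250.0,220.0,2.5
oil_palm,100.0,620.0,12.0
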