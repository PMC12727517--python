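taxon_group,food_type,mean,sd
mammal,invertebrate,0.85,0.05
mammal,vertebrate,0.90,0.04
mammal,carrion,0.85,0.05
mammal,fruit,0.70,0.08
mammal,nectar,0.95,0.03
mammal,seed,0.80,0.06
mammal,foliage,0.50,0.10
bird,invertebrate,0.78,0.06
bird,vertebrate,0.86,0.05
bird,carrion,0.82,0.06
bird,fruit,0.65,0.08
bird,nectar,0.95,0.03
bird,seed,0.75,0.07
bird,foliage,0.40,0.10
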