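function_id,aggregate_id,taxon_class,food_type,diet_min,lifestyles,mass_min_g,mass_max_g,grass_min,grass_max,herd_min,requires_large_herbivore
seed_dispersal_bird,seed_dispersal,bird,fruit,0.25,*,,,,,,
pollination_bird,pollination,bird,nectar,0.25,*,,,,,,
granivory_bird,granivory,bird,seed,0.25,*,,,,,,
aerial_invertivory_bird,insectivory,bird,invertebrate,0.25,aerial,,,,,,
insessorial_invertivory_bird,insectivory,bird,invertebrate,0.25,insessorial|arboreal,,,,,,
terrestrial_invertivory_bird,insectivory,bird,invertebrate,0.25,terrestrial|fossorial,,,,,,
aquatic_carnivory_bird,carnivory,bird,vertebrate,0.25,aquatic,,,,,,
raptorial_carnivory_bird,carnivory,bird,vertebrate,0.25,aerial|insessorial|terrestrial|arboreal,,,,,,
scavenging_bird,scavenging,bird,carrion,0.25,*,,,,,,
grazing_bird,grazing,bird,foliage,0.25,aquatic,,,,,,
cavity_creation_bird,engineering,bird,invertebrate,0.5,insessorial|arboreal,,,,,,
grazing_mammal,grazing,mammal,foliage,0.25,*,,,0.5,,,true
browsing_mammal,browsing,mammal,foliage,0.25,*,,,,0.5,,true
nutrient_dispersal_mammal,nutrient_dispersal,mammal,,,*,,,,,10,true
megafauna_impacts_mammal,engineering,mammal,,,*,65000,,,,,
apex_carnivory_mammal,carnivory,mammal,vertebrate,0.5,*,15000,,,,,
scavenging_mammal,scavenging,mammal,carrion,0.25,*,,,,,,
insectivory_mammal,insectivory,mammal,invertebrate,0.25,*,,,,,,
seed_dispersal_mammal,seed_dispersal,mammal,fruit,0.25,*,,,,,,
pollination_mammal,pollination,mammal,nectar,0.25,*,,,,,,
granivory_mammal,granivory,mammal,seed,0.25,*,,,,,,
soil_disturbance_mammal,engineering,mammal,,,fossorial,,,,,,
canopy_engineering_mammal,engineering,mammal,,,arboreal,1000,,,,,
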