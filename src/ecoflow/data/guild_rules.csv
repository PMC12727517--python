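guild_id,taxon_class,diet_category,lifestyle,large_herbivore,priority
bird_carnivore,bird,carnivore,*,*,10
bird_aerial_insectivore,bird,invertivore,aerial,*,5
bird_insectivore,bird,invertivore,*,*,10
bird_scavenger,bird,scavenger,*,*,10
bird_frugivore,bird,frugivore,*,*,10
bird_nectarivore,bird,nectarivore,*,*,10
bird_granivore,bird,granivore,*,*,10
waterbird_herbivore,bird,folivore,aquatic,*,5
bird_herbivore,bird,folivore,*,*,10
bird_omnivore,bird,omnivore,*,*,10
mammal_carnivore,mammal,carnivore,*,*,10
mammal_insectivore,mammal,invertivore,*,*,10
mammal_scavenger,mammal,scavenger,*,*,10
arboreal_frugivore,mammal,frugivore,arboreal,*,5
mammal_frugivore,mammal,frugivore,*,*,10
mammal_nectarivore,mammal,nectarivore,*,*,10
large_terrestrial_herbivore,mammal,folivore,*,true,1
fossorial_herbivore,mammal,folivore,fossorial,*,5
arboreal_herbivore,mammal,folivore,arboreal,*,5
small_terrestrial_herbivore,mammal,folivore,*,*,10
mammal_granivore,mammal,granivore,*,*,10
mammal_omnivore,mammal,omnivore,*,*,10
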