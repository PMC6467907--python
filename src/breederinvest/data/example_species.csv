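species,taxon_group,n_offspring,offspring_mass,breeder_mass,brood_masses,source
gafftopsail_catfish,fish,55,1.5,1100,,illustrative
loggerhead_sea_turtle,reptile,100-126,20,135000,,illustrative
red_winged_blackbird,bird,3-4,35,41.5,,illustrative
african_elephant,mammal,1,600000,3000000,,illustrative
great_white_shark,fish,2-10,20000,700000,,illustrative
shedao_pit_viper,reptile,4,10,200,,illustrative
fire_ant,social insect,250000,0.01,0.015,0.01;0.008;0.002;0.001;0.001,illustrative
honey_bee,social insect,150000,0.1,0.18,0.12;0.1;0.02;0.02;0.02,illustrative
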