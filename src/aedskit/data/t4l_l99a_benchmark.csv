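ligand,experiment,experiment_err,aeds_full,aeds_full_err,aeds_groups,aeds_groups_err,aeds_helix
indene,-22.84,0.04,-21.2,0.9,-21.9,0.7,-24.2
indole,-20.46,0.25,-20.7,1.4,-20.9,1.2,-20.7
benzofurane,-22.84,0.12,-17.3,0.6,-18.1,1.0,-18.5
benzene,-21.71,0.67,-19.2,0.8,-19.7,0.9,-17.2
ortho-xylene,-19.25,0.25,-20.9,1.4,-19.8,0.6,-21.9
para-xylene,-19.54,0.25,-23.5,0.9,-22.6,0.2,-23.2
toluene,-22.97,0.25,-23.7,0.4,-23.5,0.4,-23.3
N-propyl-benzene,-27.57,0.08,-29.4,0.7,-28.4,0.1,-26.7
ethylbenzene,-24.10,0.29,-23.1,0.4,-22.8,1.0,-22.3
isobutylbenzene,-27.24,0.25,-27.0,0.8,-28.3,0.4,-28.3
N-butyl-benzene,-28.03,0.08,-30.6,1.0,-30.6,0.6,-30.0
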