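# DRM activity catalog, version 1
# code	label	weight_pct	net_offset
religious_activity	Religious activity	30.6	0.39
reading	Reading	10.0	0.36
exercise_walk	Exercising or leisurely walk	8.7	0.32
grooming_bathing	Grooming or bathing (self)	31.2	0.14
watching_tv	Watching TV	20.0	0.13
chatting	Chatting with someone	58.0	0.07
working	Working	25.7	0.05
eating	Eating	72.9	0.03
walking_somewhere	Walking somewhere	15.3	-0.02
rest	Rest	65.0	-0.04
housework	Doing housework	32.9	-0.08
preparing_food	Preparing food	16.0	-0.13
watching_children	Watching children	12.2	-0.20
intimate_relations	Intimate relations/sex	0.1	0.46
listening_radio	Listening to the radio	2.0	0.01
other_leisure	Other leisurely activity	3.4	-0.04
playing	Playing	0.6	0.40
providing_care	Providing care to someone	2.1	-0.39
shopping	Shopping	1.7	0.27
subsistence_farming	Subsistence farming	1.8	-0.63
travel_bicycle	Travelling by bicycle	0.1	-1.34
travel_vehicle	Travelling by car/bus/train	0.2	-0.36
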