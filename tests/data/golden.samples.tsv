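sample_id	glucose_raw	draw_time	fasting_hours	sex	age	centre	array	PC1	PC2	PC3	PC4	PC5	PC6	PC7	PC8	PC9	PC10	chronotype	insomnia	sleep_duration	napping	daytime_dozing	ease_awakening
S000000	6.09006	10:48:49	1	M	63	C1	axiom_initial	0.731004	-0.961271	-0.118371	0.468621	-0.402059	-0.345006	1.59175	0.535815	-1.05868	0.470292	more_morning	never	short	never	never	very_easy
S000001	5.90403	08:10:21	5	M	63	C5	axiom_full	-0.667576	1.09094	-1.13244	0.665067	-0.627446	0.737769	-0.89205	-0.972945	1.53062	-1.63257	more_evening	sometimes	normal	sometimes	never	fairly_easy
S000002	5.70134	13:29:44	2	M	62	C4	axiom_initial	0.715844	-0.349493	1.92319	-0.802466	-0.678182	0.756577	0.661591	-0.832364	1.245	1.19471	more_morning	sometimes	normal	never	never	fairly_easy
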