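branch	rank	term	go_id	n11	n12	n21	n22	corrected_p
process	1	Translation	6412	37	48	305	5712	3.57e-23
process	2	Ribosome biogenesis and assembly	42254	20	65	311	5706	5.03e-7
process	3	RNA metabolic process	16070	21	64	664	5353	0.01
process	4	Organelle organization and biogenesis	6996	30	55	1230	4787	0.04
function	1	Structural molecule activity	5198	31	54	304	5712	3.95e-17
function	2	Translation regulator activity	45182	5	80	47	5969	0.01
function	3	RNA binding	3723	10	75	225	5791	0.03
component	1	Ribosome	5840	33	52	307	5710	5.56e-19
component	2	Cytoplasm	5737	59	26	2701	3316	1.05e-4
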