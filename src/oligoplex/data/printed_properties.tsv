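name	kind	length	gc	tm	dg	any	end3
BruCo5F	primer	21	47.2	60.0	0.8	2	2
BruCo5R	primer	21	42.9	59.1	0	4	2
BruCo6F	primer	21	42.9	60.2	0.5	4	2
BruCo6R	primer	21	47.7	60.7	1.0	3	0
BosCo7F	primer	21	52.4	60.0	0.7	4	1
BosCo7R	primer	24	41.7	60.3	0.7	6	4
BosCo8F	primer	22	50.0	60.1	0.7	6	4
BosCo8R	primer	22	50.0	60.7	0.9	4	2
BosCo9F	primer	23	43.5	60.1	0.9	3	3
DecCo10F	primer	22	40.9	59.8	0.7	4	1
DecCo10R	primer	20	40.0	58.0	0.9	3	0
DecCo11F	primer	24	41.7	60.4	0.9	4	1
DecCo11R	primer	24	41.7	58.9	1.0	6	2
ObsCo12F	primer	21	57.1	62.8	1.0	3	1
ObsCo12R	primer	24	41.7	58.8	0.9	3	0
ObsCo13F	primer	21	47.6	59.0	0	6	4
ObsCo13R	primer	21	42.9	60.8	1.0	6	1
PeaCo14F	primer	21	47.6	59.6	0.9	3	1
PeaCo14R	primer	21	47.6	59.2	0.9	5	3
PeaCo15F	primer	21	52.4	61.5	0.8	2	0
DecCo11P	probe	27	41	-	1.0	8	0
BruCo5P	probe	25	48	-	0.9	3	0
ObsCo12P	probe	23	56	-	0.9	6	4
BosCo8P	probe	24	58	-	1.0	4	2
PeaCo14P	probe	21	62	-	0.8	5	0
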