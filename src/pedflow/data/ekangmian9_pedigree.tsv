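child	parent1	parent2	role
Lone Star			exotic_founder
Deltapine 15			exotic_founder
Stoneville 2B			exotic_founder
Delfos			exotic_founder
Foster			exotic_founder
52-128			exotic_founder
Guannong 1			exotic_founder
Xuzhou 209			exotic_founder
Shanmian 7			exotic_founder
CCRI4			exotic_founder
Shan 5012			exotic_founder
Jinyu 3	Guannong 1	Lone Star	backbone
Jin 3-34-3	Jinyu 3	52-128	backbone
Jinmian 2	Jin 3-34-3		backbone
Ejing 1	Jinmian 2	Deltapine 15	backbone
I-Delfos-Foster	Delfos	Foster	hybrid
I-Stoneville2B-DF	Stoneville 2B	I-Delfos-Foster	hybrid
I-CCRI4-Shan5012	CCRI4	Shan 5012	hybrid
Zhong 7263	I-CCRI4-Shan5012	I-Stoneville2B-DF	backbone
MO-3	Xuzhou 209	Shanmian 7	backbone
86-1	Xuzhou 209		backbone
I-Ejing1-Zhong7263	Ejing 1	Zhong 7263	hybrid
Ekangmian 9	I-Ejing1-Zhong7263	MO-3	backbone
Zhong 309	Ekangmian 9	86-1	elite
Zhong 053	Ekangmian 9		elite
Zhong 392326	Ekangmian 9	Jinmian 2	elite
9053	Ekangmian 9		elite
Zhong 9018	Ekangmian 9	MO-3	elite
1638	Ekangmian 9		elite
ZhongCJ 377126	Ekangmian 9	Ejing 1	elite
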