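taxon	oldest_ma	youngest_ma	extant	confidence	region
Chavinziphius	6.93	6.71	0	high	Peru
Ninoziphius	5.93	3.9	0	high	Peru
Chimuziphius	8.9	8.5	0	high	Peru
Notoziphius	10	10	0	high	Argentina
Messapicetus	10.5	8.14	0	high	Peru; Italy; Maryland (USA)
Ziphirostrum	9.5	7.5	0	high	Belgium
Aporotus_dicyrtus	23.03	2.58	0	low	Belgium
Aporotus_recurvirostris	23.03	2.58	0	low	Belgium
Beneziphius	23.03	2.58	0	low	Belgium
Choneziphius	9.5	4.4	0	high	Belgium; Portugal; Spain
Globicetus	6.1	4.4	0	high	Portugal; Spain
Imocetus	6.1	4.4	0	high	Portugal
Tusciziphius	6.1	3.84	0	high	Portugal; Spain; South Carolina (USA); Italy
Tasmacetus	0	0	1	high	southern oceans
Nazcacetus	7.55	7.3	0	high	Peru
Archaeoziphius	15	13.2	0	high	Belgium
Microberardius	15.97	2.58	0	low	South Africa
Berardius	0	0	1	high	antitropical
Ziphius	0	0	1	high	cosmopolitan
Izikoziphius	15.97	2.58	0	low	South Africa
Nenga	15.97	2.58	0	low	South Africa
Pterocetus	15.97	2.58	0	low	South Africa
Xhosacetus	15.97	2.58	0	low	South Africa
Khoikhoicetus	15.97	2.58	0	low	South Africa
Ihlengesi	15.97	2.58	0	low	South Africa
Africanacetus	15.97	2.58	0	low	South Africa; sub-Antarctic Indian Ocean
Mesoplodon	0	0	1	high	cosmopolitan
Hyperoodon	0	0	1	high	antitropical
Physeter	0	0	1	high	cosmopolitan
Tursiops	0	0	1	high	cosmopolitan
Squaloziphius	23.03	2.58	0	low	synthetic outgroup placeholder
Eurhinodelphis	23.03	2.58	0	low	synthetic outgroup placeholder
Xiphiacetus	23.03	2.58	0	low	synthetic outgroup placeholder
Schizodelphis	23.03	2.58	0	low	synthetic outgroup placeholder
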