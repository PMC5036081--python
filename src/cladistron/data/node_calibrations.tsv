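clade	kind	max_ma	min_ma	members
Ziphiidae	mrca	17.5	11.9	Chavinziphius Ninoziphius Chimuziphius Notoziphius Messapicetus Ziphirostrum Aporotus_dicyrtus Aporotus_recurvirostris Beneziphius Choneziphius Globicetus Imocetus Tusciziphius Tasmacetus Nazcacetus Archaeoziphius Microberardius Berardius Ziphius Izikoziphius Nenga Pterocetus Xhosacetus Khoikhoicetus Ihlengesi Africanacetus Mesoplodon Hyperoodon
Messapicetus_clade	mrca	17.5	13.8	Chimuziphius Notoziphius Messapicetus Ziphirostrum Aporotus_dicyrtus Aporotus_recurvirostris Beneziphius Choneziphius Globicetus Imocetus Tusciziphius
Crown_Ziphiidae	mrca	17	17	Tasmacetus Nazcacetus Archaeoziphius Microberardius Berardius Ziphius Izikoziphius Nenga Pterocetus Xhosacetus Khoikhoicetus Ihlengesi Africanacetus Mesoplodon Hyperoodon
Berardiinae	mrca	15	13.2	Archaeoziphius Microberardius Berardius
Mesoplodon	stem	4.86	3.9	Mesoplodon
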