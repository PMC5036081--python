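taxon,area
Chavinziphius,A
Ninoziphius,A
Chimuziphius,A
Notoziphius,B
Messapicetus,A
Ziphirostrum,A
Aporotus_dicyrtus,A
Aporotus_recurvirostris,A
Beneziphius,A
Choneziphius,A
Globicetus,A
Imocetus,A
Tusciziphius,A
Tasmacetus,B
Nazcacetus,A
Archaeoziphius,A
Microberardius,B
Berardius,D
Ziphius,C
Izikoziphius,B
Nenga,B
Pterocetus,B
Xhosacetus,B
Khoikhoicetus,B
Ihlengesi,B
Africanacetus,B
Mesoplodon,C
Hyperoodon,D
Physeter,?
Tursiops,?
Squaloziphius,?
Eurhinodelphis,?
Xiphiacetus,?
Schizodelphis,?
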