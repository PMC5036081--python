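(Physeter,(Tursiops,((Eurhinodelphis,(Xiphiacetus,Schizodelphis)),(Squaloziphius,(Chavinziphius,(Ninoziphius,(((Chimuziphius,Notoziphius),(Messapicetus,(Ziphirostrum,((Aporotus_dicyrtus,Aporotus_recurvirostris),(Beneziphius,(Choneziphius,(Globicetus,(Imocetus,Tusciziphius)))))))),(Tasmacetus,(Nazcacetus,((Archaeoziphius,(Microberardius,Berardius)),((Ziphius,Izikoziphius),(Nenga,((Pterocetus,Xhosacetus),(Khoikhoicetus,(Ihlengesi,(Africanacetus,(Mesoplodon,Hyperoodon)))))))))))))))));
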