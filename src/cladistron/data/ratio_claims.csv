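name,numerator,denominator,printed
MUSM 2538 temporal fossa / neurocranium,119,290,0.41
MUSM 2538 left / right premaxillary sac fossa,44,53,0.82
MUSM 1609 B/A,214,798,0.27
MUSM 1609 C/A,57,798,0.07
MUSM 1609 D/A,330,798,0.41
MUSM 1037 B/A,217,844,0.26
MUSM 1037 C/A,69,844,0.08
MUSM 1037 D/A,385,844,0.46
MUSM 1038 B/A,208,795,0.26
MUSM 1038 C/A,64,795,0.08
MUSM 1038 D/A,390,795,0.49
MNHN SAS941 D/A,310,685,0.45
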