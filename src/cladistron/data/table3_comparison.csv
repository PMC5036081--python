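measurement,MUSM 1609,MUSM 1037,MUSM 1038,MNHN SAS941
Length of rostrum (A),798,844,795,685*
Width of rostrum base at level antorbital notch (B),214,217,208,-
Width of rostrum at midlength (C),57,69,64,-
Length of symphyseal portion of mandible (D),330+,385,390,310
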