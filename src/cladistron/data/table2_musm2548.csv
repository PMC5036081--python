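measurement,MUSM 2548
Condylobasal length,580+
Length of rostrum,330+
Length of neurocranium,230+
Width of rostrum base at level antorbital notch,178*
Width of premaxillae at level antorbital notch,82
Preorbital width of skull,250*
Postorbital width of skull,240*
Length of antorbital process of lacrimal,29
Length of orbit,84
Total width of premaxillary sac fossae,111
Maximum width of right premaxillary sac fossa,60
Maximum width of left premaxillary sac fossa,46
Width of bony nares,60
Transverse width across premaxillary crests,125
Width right premaxillary crest,33
Width left premaxillary crest,25
Minimum distance between premaxillary crests,68
Maximum width of nasals,87
Width of right nasal,45
Width of left nasal,42
Length of medial suture between nasals,53
Minimum posterior distance between maxillae on the vertex,77
Length of medial suture between frontals on the vertex,7
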