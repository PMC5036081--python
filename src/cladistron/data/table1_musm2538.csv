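measurement,MUSM 2538
Condylobasal length,468+
Length of neurocranium,290
Width of rostrum base at level prominental notch,215
Width of rostrum base at level antorbital notch,225
Height of rostrum base at level antorbital notch,140
Width of premaxillae at level antorbital notch,88
Preorbital width of skull,340*
Postorbital width of skull,350*
Bizygomatic width of skull,368
Height of cranium,275
Length of antorbital process of lacrimal,48
Length of orbit,96
Length of temporal fossa,119
Height of temporal fossa,69
Total width of premaxillary sac fossae,110
Maximum width of right premaxillary sac fossa,53
Maximum width of left premaxillary sac fossa,44
Longitudinal distance left pmx foramen antorbital notch,36
Width of bony nares,55
Width left premaxillary crest,32
Minimum distance between premaxillary crests,62
Maximum width of nasals,78
Width of right nasal,38
Width of left nasal,36
Length of medial suture between nasals,37
Minimum posterior distance between maxillae on the vertex,69
Length of medial suture between frontals on the vertex,24
Minimum distance between temporal fossae in posterior view,235
Width of occipital condyles,114
Width of foramen magnum,35
Maximum width of right occipital condyle,42
Maximum height of right occipital condyle,63
Length of mandible,670+
Length of symphyseal portion of mandible,110+
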