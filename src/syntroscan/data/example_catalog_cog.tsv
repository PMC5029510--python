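# Example gene-family category catalog (COG namespace).
# SYNTHETIC / REPRESENTATIVE member lists: the 13 category names and the
# universal vs syntroph-associated split follow the published search scheme,
# but the family identifiers below are placeholders chosen to be plausible,
# not the curated per-category lists. Replace this file with a curated
# catalog for real analyses.
division	category	family_id
universal	G1-Ribosome and Translation Initiation	COG0048
universal	G1-Ribosome and Translation Initiation	COG0049
universal	G1-Ribosome and Translation Initiation	COG0051
universal	G1-Ribosome and Translation Initiation	COG0052
universal	G1-Ribosome and Translation Initiation	COG0080
universal	G1-Ribosome and Translation Initiation	COG0081
universal	G1-Ribosome and Translation Initiation	COG0087
universal	G1-Ribosome and Translation Initiation	COG0090
universal	G2-Ribosome Associated/Protein Modification	COG0012
universal	G2-Ribosome Associated/Protein Modification	COG0013
universal	G2-Ribosome Associated/Protein Modification	COG0016
universal	G2-Ribosome Associated/Protein Modification	COG0018
universal	G2-Ribosome Associated/Protein Modification	COG0030
universal	G2-Ribosome Associated/Protein Modification	COG0060
universal	G3-Transcription/DNA Replication	COG0085
universal	G3-Transcription/DNA Replication	COG0086
universal	G3-Transcription/DNA Replication	COG0187
universal	G3-Transcription/DNA Replication	COG0188
universal	G3-Transcription/DNA Replication	COG0202
universal	G3-Transcription/DNA Replication	COG0592
universal	G4-Unknown	COG0011
universal	G4-Unknown	COG0327
universal	G4-Unknown	COG0718
universal	G4-Unknown	COG0799
universal	G4-Unknown	COG1399
syntroph	FeS Oxidoreductases	COG0348
syntroph	FeS Oxidoreductases	COG0437
syntroph	FeS Oxidoreductases	COG0479
syntroph	FeS Oxidoreductases	COG1143
syntroph	FeS Oxidoreductases	COG1145
syntroph	Fnr	COG4656
syntroph	Fnr	COG4657
syntroph	Fnr	COG4658
syntroph	Fnr	COG4659
syntroph	Fnr	COG4660
syntroph	Fix	COG0644
syntroph	Fix	COG2025
syntroph	Fix	COG2086
syntroph	Fix	COG2440
syntroph	Confurcating Hydrogenases	COG1894
syntroph	Confurcating Hydrogenases	COG3261
syntroph	Confurcating Hydrogenases	COG3262
syntroph	Confurcating Hydrogenases	COG4624
syntroph	Other Hydrogenases	COG0374
syntroph	Other Hydrogenases	COG1740
syntroph	Other Hydrogenases	COG1941
syntroph	Other Hydrogenases	COG3259
syntroph	Membrane Hydrogenases	COG0650
syntroph	Membrane Hydrogenases	COG0651
syntroph	Membrane Hydrogenases	COG3260
syntroph	NADH Linked Formate Dehydrogenases	COG0243
syntroph	NADH Linked Formate Dehydrogenases	COG3383
syntroph	Other Formate Dehydrogenases	COG1151
syntroph	Other Formate Dehydrogenases	COG2180
syntroph	Other Formate Dehydrogenases	COG5557
syntroph	Membrane Formate Dehydrogenases	COG1526
syntroph	Membrane Formate Dehydrogenases	COG2864
syntroph	Membrane Formate Dehydrogenases	COG3301
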