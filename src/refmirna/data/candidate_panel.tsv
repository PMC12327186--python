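assay_name	assay_id	mature_sequence
hsa-let-7c-5p	478577_mir	UGAGGUAGUAGGUUGUAUGGUU
hsa-miR-100-5p	478224_mir	AACCCGUAGAUCCGAACUUGUG
hsa-miR-204-5p	478491_mir	UUCCCUUUGUCAUCCUAUGCCU
hsa-miR-25-3p	477994_mir	CAUUGCACUUGUCUCGGUCUGA
hsa-miR-26a-5p	477995_mir	UUCAAGUAAUCCAGGAUAGGCU
hsa-miR-92a-3p	477827_mir	UAUUGCACUUGUCCCGGCCUGU
U6 snRNA	001973	GTGCTCGCTTCGGCAGCACATATACTAAAATTGGAACGATACAGAGAAGATTAGCATGGCCCCTGCGCAAGGATGACACGCAAATTCGTGAAGCGTTCCATATTTT
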