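{
  "ref_id": "bacteriorhodopsin",
  "comment": "Canonical bacteriorhodopsin (Halobacterium salinarum) sequence. The 24 positions approximate the retinal-contact shell, including the Schiff-base lysine K216; replaceable configuration.",
  "ref_sequence": "QAQITGRPEWIWLALGTALMGLGTLYFLVKGMGVSDPDAKKFYAITTLVPAIAFTMYLSMLLGYGLTMVPFGGEQNPIYWARYADWLFTTPLLLLDLALLVDADQGTILALVGADGIMIGTGLVGALTKVYSYRFVWWAISTAAMLYILYVLFFGFTSKAESMRPEVASTFKVLRNVTVVLWSAYPVVWLIGSEGAGIVPLNIETLLFMVLDVSAKVGFGLILLRSRAIFGEAEAPEPSAGDGAAATSD",
  "pocket_positions": [83, 85, 86, 89, 90, 93, 115, 118, 119, 122, 138, 141, 142, 145, 148, 182, 185, 186, 189, 194, 208, 212, 215, 216]
}
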