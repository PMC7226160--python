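{
 "cited_nodes": [
  "2",
  "3",
  "12",
  "19",
  "27",
  "28",
  "33",
  "34",
  "36",
  "37",
  "38"
 ],
 "fixture_version": "1.0",
 "groups": {
  "AAP": [
   "Acholeplasma_laidlawii",
   "Candidatus_Phytoplasma_asteris_AYWB",
   "Candidatus_Phytoplasma_asteris_OY",
   "Candidatus_Phytoplasma_australiense",
   "Candidatus_Phytoplasma_mali"
  ],
  "H": [
   "Mycoplasma_agalactiae",
   "Mycoplasma_arthritidis",
   "Mycoplasma_bovigenitalium_cl-51080",
   "Mycoplasma_bovis",
   "Mycoplasma_conjunctivae",
   "Mycoplasma_fermentans",
   "Mycoplasma_hominis",
   "Mycoplasma_hyopneumoniae",
   "Mycoplasma_hyorhinis",
   "Mycoplasma_mobile",
   "Mycoplasma_ovipneumoniae",
   "Mycoplasma_pulmonis",
   "Mycoplasma_synoviae"
  ],
  "P": [
   "Mycoplasma_gallisepticum",
   "Mycoplasma_genitalium",
   "Mycoplasma_haemofelis",
   "Mycoplasma_iowae",
   "Mycoplasma_muris",
   "Mycoplasma_penetrans",
   "Mycoplasma_pneumoniae",
   "Mycoplasma_suis",
   "Ureaplasma_parvum",
   "Ureaplasma_urealyticum"
  ],
  "S": [
   "Mesoplasma_florum",
   "Mycoplasma_auris",
   "Mycoplasma_capricolum_subsp_capricolum",
   "Mycoplasma_capricolum_subsp_capripneumoniae",
   "Mycoplasma_leachii",
   "Mycoplasma_mycoides_subsp_capri",
   "Mycoplasma_putrefaciens",
   "Mycoplasma_yeatsii",
   "Spiroplasma_apis",
   "Spiroplasma_citri",
   "Spiroplasma_melliferum"
  ],
  "mycoides_cluster": [
   "Mycoplasma_capricolum_subsp_capricolum",
   "Mycoplasma_capricolum_subsp_capripneumoniae",
   "Mycoplasma_leachii",
   "Mycoplasma_mycoides_subsp_capri"
  ]
 },
 "n_species": 39,
 "reference": {
  "catalytic_positions": [
   51,
   223
  ],
  "fad_motif_pattern": "GAG[A-Z][AS]G[A-Z]E[AV]",
  "flavin_stack_position": 343,
  "folate_triad_positions": [
   308,
   309,
   310
  ],
  "id": "TrmFO_reference",
  "note": "Synthetic stand-in for the thermophile TrmFO reference used for coordinate mapping; landmark positions follow the published 1-based numbering (C51, C223, H308/R309/N310, Y343, FAD motif).",
  "sequence": "ECNFYSLGAGTAGLEALKVDEADACHEMLHVPMYFSVFETFQAGCWLDPLCCEFRFAVWRTGFVFSRHRPYHDGNKNAAMKDWMKVDMREGRWYHALISCACIRIGYGSVDQEEQYFMSFNWNRECSRQELKYRLVFMKTWPHDPGKNFLYMDLKKCPCKVRQMRHMKTYLLRVLRVRQFGERPQLLEIKLNSKESKDNALPLWDGCVIDWVYEHHDDCRDTCNPCEGYACCAFPNCVMDQPMDMPDYLQPDAYIKYGPWHYWACPTVHRYSCNHCNGANHPTPQIPCSTLGPWSQLKIETQYCKWSHRNAIAIQLEGAKMMKVEDTAKRPMFSLRGCAPSSYPTAASFDGAQPKHQRCAMLKFRQNKVFLCAFGLTPPQMCTKYKQAYYPVMIQAEGNVLFHCYICPVGNGATCRHTNNWLLREPTFANPTFVSGLHKKMGD"
 }
}
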