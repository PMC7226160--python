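((Acholeplasma_laidlawii:0.216,((Candidatus_Phytoplasma_asteris_OY:0.331,Candidatus_Phytoplasma_asteris_AYWB:0.28)n40:0.083,(Candidatus_Phytoplasma_australiense:0.223,Candidatus_Phytoplasma_mali:0.309)n41:0.161)2:0.149)3:0.143,((((Spiroplasma_citri:0.3,(Spiroplasma_melliferum:0.312,Spiroplasma_apis:0.106)n44:0.178)n43:0.152,Mesoplasma_florum:0.252)n42:0.21,(Mycoplasma_auris:0.315,((Mycoplasma_putrefaciens:0.124,Mycoplasma_yeatsii:0.224)n46:0.161,((Mycoplasma_mycoides_subsp_capri:0.118,Mycoplasma_leachii:0.153)n47:0.269,(Mycoplasma_capricolum_subsp_capricolum:0.335,Mycoplasma_capricolum_subsp_capripneumoniae:0.126)n48:0.212)33:0.071)n45:0.237)34:0.172)36:0.145,(((((Mycoplasma_agalactiae:0.276,Mycoplasma_bovis:0.263)n50:0.082,Mycoplasma_bovigenitalium_cl-51080:0.189)n52:0.191,((Mycoplasma_fermentans:0.263,(Mycoplasma_hominis:0.118,Mycoplasma_arthritidis:0.122)n55:0.161)n54:0.134,(Mycoplasma_pulmonis:0.315,Mycoplasma_mobile:0.164)n56:0.26)n53:0.061)n51:0.137,((Mycoplasma_hyorhinis:0.197,(Mycoplasma_conjunctivae:0.296,(Mycoplasma_ovipneumoniae:0.269,Mycoplasma_hyopneumoniae:0.121)19:0.111)n59:0.076)n58:0.189,Mycoplasma_synoviae:0.269)n57:0.212)27:0.148,(((Mycoplasma_pneumoniae:0.138,Mycoplasma_genitalium:0.101)n61:0.133,(Mycoplasma_gallisepticum:0.179,(Mycoplasma_penetrans:0.178,Mycoplasma_iowae:0.103)n63:0.165)n62:0.214)n60:0.138,((Ureaplasma_parvum:0.308,Ureaplasma_urealyticum:0.321)n65:0.091,(Mycoplasma_muris:0.14,(Mycoplasma_haemofelis:0.166,Mycoplasma_suis:0.128)n67:0.078)n66:0.138)n64:0.107)12:0.076)28:0.168)37:0.147)38;
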