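ligand,pubchem_cid,ic50_nM,pic50,vina_score_kcal_mol,autodock_ic50_nM,autodock_pic50,pic50_difference
Estradiol,5757,46,7.34,-10,52.0,7.28,-0.0535
Raloxifene,5035,7.7,8.11,-11.1,8.79,8.06,-0.0575
QYA,145949437,5000,5.30,-6.97,127000,3.90,-1.40
Benzoxazole,9228,5.4,8.27,-11.3,6.18,8.21,-0.0586
Hydroxytamoxifen,449459,23000,4.64,-6.23,36700,4.44,-0.23
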