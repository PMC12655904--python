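ligand,pubchem_cid,ic50_nM,pic50,vina_score_kcal_mol,autodock_ic50_nM,autodock_pic50,pic50_difference
Hydroxytamoxifen,449459,40,7.40,-9,278.38,6.60,-0.844
Caffeic Acid,689043,120000,3.92,-6.4,21800,4.66,0.74
Bazedoxifene,154257,26,7.59,-8.5,643.90,6.19,-1.39
Lasofoxifene,216416,1.08,8.97,-8.4,761.48,6.19,-2.85
Fulvestrant,104741,4.4,8.36,-8.3,900.52,6.05,-2.31
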