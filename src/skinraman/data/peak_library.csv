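# Stratum-corneum Raman peak library (fingerprint region, 400-1800 cm-1).
# Centers and assignments are literature band positions for human skin;
# widths (HWHM) and base amplitudes are synthetic defaults for the simulator,
# not measured quantities.
center_cm1,width_cm1,base_amplitude,assignment,references
543,7,0.25,"nu(S-S), cholesterol","skin Raman band tables"
618,6,0.20,"nu(C-C) twisting (protein)","skin Raman band tables"
702,6,0.30,"cholesterol","skin Raman band tables"
755,6,0.25,"symmetric breathing of tryptophan","skin Raman band tables"
773,5,0.15,"nu(C-C) ring breathing","skin Raman band tables"
787,5,0.20,"nucleic acid (O-P-O backbone)","skin Raman band tables"
855,7,0.45,"nu(C-C) of proline, delta(CCH) of protein; NMF region","skin Raman band tables"
885,7,0.30,"pyrrolidone carboxylic acid (NMF)","skin Raman band tables"
906,6,0.30,"tyrosine (amino acid)","skin Raman band tables"
937,8,0.40,"nu(C-C) alpha-helix conformation (protein)","skin Raman band tables"
960,6,0.30,"delta(CCH) olefinic","skin Raman band tables"
980,7,0.35,"nu(C-C) beta-sheet (protein), CH bending (lipid)","skin Raman band tables"
1003,4,0.70,"nu(C-C) ring breathing of phenylalanine","skin Raman band tables"
1063,7,0.45,"nu(C-C) skeletal stretching (lipid)","skin Raman band tables"
1078,8,0.40,"nu(C-C)/nu(C-O), phospholipids","skin Raman band tables"
1126,7,0.30,"nu(C-C) skeletal, lipid/protein","skin Raman band tables"
1154,7,0.25,"nu(C-C), delta(COH) (lipid)","skin Raman band tables"
1207,7,0.25,"tryptophan, phenylalanine (protein)","skin Raman band tables"
1270,10,0.45,"amide III (alpha-helix, protein)","skin Raman band tables"
1296,8,0.50,"ceramide III CH2 twist (SC lipid)","skin Raman band tables"
1340,9,0.30,"CH2/CH3 wagging, nucleic acid modes","skin Raman band tables"
1379,7,0.25,"delta(CH3) symmetric (lipid)","skin Raman band tables"
1420,8,0.35,"nu(C=O) of COO- (aspartate/glutamate)","skin Raman band tables"
1452,9,0.80,"delta(CH3)/delta(CH2) (proteins and lipids)","skin Raman band tables"
1552,8,0.25,"delta(NH), nu(CN) amide II (protein)","skin Raman band tables"
1586,7,0.20,"nu(C=C) olefinic (protein)","skin Raman band tables"
1618,7,0.25,"nu(C=C) tryptophan (protein)","skin Raman band tables"
1645,10,0.60,"O-H water and amide I alpha-helix (protein)","skin Raman band tables"
1655,12,1.00,"nu(C=O) amide I, keratin (protein); lipid nu(C=C)","skin Raman band tables"
1716,8,0.20,"nu(C=O) OH (aspartate/glutamate)","skin Raman band tables"
1768,7,0.12,"nu(COO)","skin Raman band tables"
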