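target,clone,scaffold,sequence,kd_um,elisa_signal,sn_ratio
Notch2Long,N2L-EET-63,EETI-II,GCEQSTWWAPCKQDSDCLAGCVCYQRWHCG,n/d,3.9,30.8
Notch2Long,N2L-EET-57,EETI-II,GCDQGHSSGWQKCKQDSDCLAGCVCWFRWHCG,n/d,1.7,17.1
Notch2Long,N2L-EET-83,EETI-II,GCEQSTWWAPCKQDSDCLAGCVCYLRWHCG,n/d,3.9,30.8
Notch2Long,N2L-EET-62,EETI-II,GCGQTTAWEPCKQDSDCLAGCVCFMRWHCG,n/d,2.8,32.6
Notch2Long,N2L-EET-03,EETI-II,GCGWTLWHCKQDSDCLAGCVCEPIWWCD,43.7,0.3,3.1
Notch2Long,N2L-EET-36,EETI-II,GCEVVMERCKQDSDCLAGCVCWYWTSCG,n/d,2.2,18.3
Notch2Long,N2L-EET-28,EETI-II,GCKQFGNQWICKQDSDCLAGCVCGPNGFCG,n/d,1.6,13.7
Notch2Long,N2L-EET-29,EETI-II,GCGWTLAHCKQDSDCLAGCVCQPRWVCG,102.5,0.6,4.4
Notch2NRR,N2N-EET-57,EETI-II,GCRPRWGGWHCKQDSDCLAGCVCGPNGFCG,132.1,3.8,30.9
Notch2NRR,N2N-EET-33,EETI-II,GCQQRRWGGWQQCKQDSDCLAGCVCGPNGFCG,55.6,3.6,28.9
Notch2NRR,N2N-EET-45,EETI-II,GCGQQRWGGWPLCKQDSDCLAGCVCGPNGFCG,55.9,3.5,14.9
Notch2NRR,N2N-EET-63,EETI-II,GCMPRYGGWHCKQDSDCLAGCVCGPNGFCG,166.1,1.5,21.3
Notch2NRR,N2N-EET-n3,EETI-II,GCRPRFKGWTCKQDSDCLAGCVCGPNGFCG,180.1,2.1,33.1
Notch2NRR,N2N-EET-n13,EETI-II,GCGQKRMGGWQWCKQDSDCLAGCVCGPNGFCG,12.0,3.4,53.9
HtrA1,HtrA1_EET76,EETI-II,GCHRPWWQLWGLCKQDSDCLAGCVCGPNGFCG,9.5,1.0,13.7
HtrA1,HtrA1_CirA65,Circulin-A,WIPCISAALGCSCKNKVCYIFSKHLCGESCV,2.7,2.2,33.9
HtrA1,HtrA1_CirA38,Circulin-A,WIPCISAALGCSCKNKVCYFLYQICGESCV,2.5,2.1,31.9
Notch2NRR,N2N-AVR-n6,AVR9,AFDCLGQCGRCDFHKLQCVWSNRHSPYCNSSCTR,0.8,3.3,39.3
Notch2NRR,N2N-AVR-19,AVR9,AFDCLGQCGRCDFHKLQCVPYSWTYKQYCNSSCTR,9.4,2.6,35.7
HtrA1,HtrA1_AVR61,AVR9,AFDCLGQCGRCDFHKLQCVMVYFIHMTKPYCNSSCTR,>20,1.7,24.4
HtrA1,HtrA1_AVR62,AVR9,AFDCLGQCGRCDFHKLQCVRQIVWRVINLSHYCNSSCTR,>15,1.6,19.5
CD28-Fc,CD28_Hwtx1,Huwentoxin,ACKGVFDACTVFEVTDTGVLECCPNAVCSDKHKWCKWKL,n/d,1.4,9.8
HtrA1,HtrA1_HwTx69,Huwentoxin,ACKGVFDACTWKNWRQSRSRECCPNAVCSDKHKWCKWKL,3.7,0.9,9.6
PCSK9 dCRD,PCSK9_CnTx1,Conotoxin-MVIIA,ECKGKGAKCSYYMGIDKGYVNYCCTGSCRSGKC,4.5,2.0,29.7
PCSK9 dCRD,PCSK9_CnTx2,Conotoxin-MVIIA,ECKGKGAKCSFMTRQGVQTWCCTGSCRSGKC,2.8,1.7,25.9
HtrA1,HtrA1_CnTx83,Conotoxin-MVIIA,ECKGKGAKCSIQWSVYPWKVCCTGSCRSGKC,6.4,1.1,16.1
Fz7CRD-Fc,Fz7-Fc_CnTx1,Conotoxin-MVIIA,ECKGKGAKCSEYWIPMVGWVCCTGSCRSGKC,n/d,5.1,32.7
PCSK9,PCSK9FL_CBD1,CBD,GPTQSNYGMCGGIGYSGPTVCASGTTCQVLYPTTSRCLPGAS,n/d,1.1,17.7
PCSK9,PCSK9FL_CBD2,CBD,GPTQSKYGMCGGIGYSGPTVCASGTTCQVLDPYTSQCLPGAS,3.6,1.9,26.8
Her3-Fc,Her3-Fc_CBD1,CBD,GPTQSWQGRCGGIGYSGPTVCASGTTCQVLTPYWSECLPGAS,27.0,1.7,20.2
HtrA1,HtrA1_CBDwt46,CBD,GPTQSHYGQCGGWGYTGWYQCASGTTCQGPRSRLSQCLPGAS,n/d,2.6,25.9
HtrA1,HtrA1_CBDamy86,CBD,GPTQSFWGWCGGIGYVGGRYCSGTTCQRPDAHWSQCLPGAS,158.0,1.6,22.8
Her3-Fc,Her3-Fc_ChTx1,Charybdotoxin,VSCTTSKECWSVCQRLHNTSWGEQCVTKFCKCEE,>10,1.7,22.6
Her3-Fc,Her3-Fc_ChTx2,Charybdotoxin,VSCTTSKECWSVCQRLHNTSWLGSCMERFCKCVD,1.5,1.6,24.3
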