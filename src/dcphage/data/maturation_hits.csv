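clone,scaffold,sequence,kd_um,elisa_signal,sn_ratio,generation,parent
N2L.EET03,EETI-II,GCGWTLWHCKQDSDCLAGCVCEPIWWCG,43.7,0.4,3.1,0,
N2L.EET03.10,EETI-II,GCGWTLRHCKQDSDCLAGCVCRPIWYCG,4.5,3.0,48.4,1,N2L.EET03
N2L.EET31,EETI-II,GCIKSHLWCKQDSDCLAGCVCEVWIQCG,>100,0.1,0.4,0,
N2L.EET31.32,EETI-II,GCIKSHLWCPSDERCLAGCVCEVWIQCG,,0.5,3.7,1,N2L.EET31
N2L.EET31.43,EETI-II,GCIKSHLWCKQDSDCEAGCICEVWIQCG,,0.7,5.1,1,N2L.EET31
N2L.EET31.43.30,EETI-II,GCIKSHLWCPHGGRCEAGCICEVWIQCG,,2.2,10.7,2,N2L.EET31.43
N2L.EET31.43.75,EETI-II,GCIKSHLWCDPRKDCEAGCICEVWIQCG,0.41,2.1,10.3,2,N2L.EET31.43
N2L.EET31.43.24,EETI-II,GCIKSHLWCPKTSDCEAGCICEVWIQCG,3.5,2.1,10.5,2,N2L.EET31.43
N2L.EET31.43.35,EETI-II,GCIKSHLWCPPPRRCEAGCICEVWIQCG,,2.1,11.6,2,N2L.EET31.43
N2L.EET31.43.18,EETI-II,GCIKSHLWCHPKLDCEAGCICEVWIQCG,,2.1,10.2,2,N2L.EET31.43
N2L.EET31.43.78,EETI-II,GCIKSHLWCDPRVSCEAGCICEVWIQCG,,1.9,10.3,2,N2L.EET31.43
N2L.EET31.43.88,EETI-II,GCIKSHLWCDPRKSCEAGCICEVWIQCG,,1.9,10.2,2,N2L.EET31.43
N2L.EET31.43.73,EETI-II,GCVRSHLWCKQDSDCEAGCICEVWIKCG,,2.3,11.0,2,N2L.EET31.43
N2L.EET31.43.64,EETI-II,GCIRSHVWCKQDSDCEAGCICEVWVKCG,,2.0,8.8,2,N2L.EET31.43
N2L.EET31.43.43,EETI-II,GCIRSHVWCKQDSDCEAGCICEIWIQCG,3.5,2.0,10.2,2,N2L.EET31.43
N2L.EET31.32.13,EETI-II,GCIKSHLWCPRDSDCLAGCVCEVWIQCG,35,2.2,10.2,2,N2L.EET31.32
N2L.EET31.32.29,EETI-II,GCIKSHLWCPRHEKCLAGCVCEVWIRCG,,2.0,9.3,2,N2L.EET31.32
N2L.EET31.32.70,EETI-II,GCIRSHLWCPPSASCLAGCVCEVWIQCG,1.0,1.9,7.3,2,N2L.EET31.32
N2L.EET31.32.33,EETI-II,GCIKSHLWCPRAEKCLAGCICEVWIQCG,,1.9,9.3,2,N2L.EET31.32
N2L.EET31.32.48,EETI-II,GCIKSHLWCPGKERCLAGCICEIWIQCG,,1.9,7.2,2,N2L.EET31.32
N2L.EET31.32.21,EETI-II,GCIKSHLWCPPSDYCLAGCVCEVWIQCG,,1.8,9.1,2,N2L.EET31.32
N2L.EET31.32.80,EETI-II,GCIRSQLWCPSDERCLAGCVCEVWIKCG,,2.1,7.6,2,N2L.EET31.32
N2L.EET31.32.85,EETI-II,GCVRSHVWCPSDERCLAGCVCEIWIRCG,,2.0,4.3,2,N2L.EET31.32
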