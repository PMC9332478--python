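compound_id,compound,class,purity,supplier,loq,lod,slope,intercept,r_squared
1,ethyl acetate,Ester,0.998,Sigma-Aldrich,"121,137","40,379",30.114,"-191,619",0.9811
5,isoamyl acetate,Ester,0.95,Sigma-Aldrich,433.125,144.375,0.0102,-31.932,0.918
9,diethyl succinate,Ester,0.99,Sigma-Aldrich,99.9375,33.3125,0.0081,-4.7535,0.9829
14,benzaldehyde,Aldehyde,0.99,Sigma-Aldrich,300,100,0.0068,-188.12,0.9911
20,propionic acid,Acid,0.995,Sigma-Aldrich,6135,2045,0.5732,1246.3,0.9697
22,isovaleric acid,Acid,0.99,Sigma-Aldrich,116.25,38.75,0.0012,13.158,0.9939
24,caproic acid,Acid,0.995,Sigma-Aldrich,2437.5,812.5,0.0911,507.9,0.9661
25,octanoic acid,Acid,0.99,Sigma-Aldrich,6761.25,2253.75,0.0438,902,0.9837
28,phenethyl alcohol,Alcohol,0.99,Sigma-Aldrich,"30,825","10,275",0.1457,"-18,131",0.9953
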