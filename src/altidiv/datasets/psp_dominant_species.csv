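altitude_class,species,family,status,endemism,rden_pct,rfreq_pct,rdom_pct,ivi
0-400,Cullenia rosayroana,Malvaceae,LC,endemic,7.47,1.08,10.72,19.27
0-400,Alstonia macrophylla,Apocynaceae,NE,exotic,10.25,0.54,6.92,17.72
0-400,Syzygium firmum,Myrtaceae,LC,native,4.56,1.08,9.24,14.89
400-800,Shorea affinis,Dipterocarpaceae,VU,endemic,10.33,1.74,12.52,24.59
400-800,Durio ceylanicus,Malvaceae,LC,endemic,9.25,1.74,13.02,24.01
400-800,Mesua thwaitesii,Calophyllaceae,LC,endemic,11.95,1.74,4.99,18.68
800-1200,Shorea gardneri,Dipterocarpaceae,VU,endemic,5.46,1.72,28.37,35.56
800-1200,Shorea trapezifolia,Dipterocarpaceae,VU,endemic,7.10,1.72,16.00,24.82
800-1200,Myristica dactyloides,Myristicaceae,LC,native,6.91,1.72,8.51,17.14
1200-1800,Magnolia nilagirica,Magnoliaceae,VU,native,3.25,1.22,24.53,29.00
1200-1800,Allophylus zeylanicus,Sapindaceae,LC,endemic,17.22,1.22,6.25,24.68
1200-1800,Neolitsea fuscata,Lauraceae,VU,endemic,9.84,1.22,10.15,21.21
above-1800,Ilex walkeri,Aquifoliaceae,LC,native,10.98,2.90,14.56,28.44
above-1800,Symplocos bractealis,Symplocaceae,EN,endemic,11.47,2.90,8.20,22.57
above-1800,Rhododendron arboreum,Ericaceae,VU,endemic,10.98,1.45,8.91,21.34
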