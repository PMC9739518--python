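compound,threshold_ug_per_L,descriptors,oav_mean_RG,oav_std_RG,oav_mean_RP,oav_std_RP
Ethyl isovalerate,6.89,Fruity,6484.69,6010.65,3683.28,6341.29
Ethyl butyrate,82.00,"Apple, fruity",886.24,362.32,986.18,509.55
Ethyl valerate,27.00,"Fruity, apple, strawberry",414.43,228.42,484.91,317.67
2-Methylbutyraldehyde,17.00,"Grass, plant, malt",372.55,387.49,267.10,437.57
Acetaldehyde,1200.00,Pungent,351.96,141.28,247.22,136.93
"1,1-Diethoxyethane",2090.00,Fruity,347.55,135.50,246.23,132.20
Ethyl octanoate,12.90,"Pineapple, fruity, floral",250.84,315.34,233.13,329.38
3-Hydroxy-2-butanone,259.00,"Fatty, buttery, sweet",174.26,107.57,123.27,97.07
Isobutyraldehyde,34.69,"Pungent, malt, green",121.43,75.02,62.88,65.93
3-Methylbutyraldehyde,980.00,"Grass, malt",102.88,61.73,65.08,63.47
Ethyl isobutyrate,57.50,"Fruity, sweet",87.45,40.15,65.31,32.61
Ethyl acetate,32600.00,"Fruity, buttery, orange",67.09,12.75,64.51,15.41
Isoamyl acetate,93.93,Fruity,63.74,39.15,41.20,40.46
Butyric acid,964.00,"Sweaty, acidic, mud",57.50,18.50,66.69,30.54
2-Methyl butanol,16.00,"Cocoa, nutty",45.35,129.84,60.65,130.94
Ethyl palmitate,2000.00,Nutty,40.57,23.27,100.01,376.23
2-Pentanone,194000.00,Wine,26.56,42.05,35.71,89.37
1-Butanol,2730.00,"Alcoholic, sweet",22.01,14.26,19.85,19.79
Hexanoic acid,13300.00,Sweaty,19.80,16.65,14.14,10.97
Isobutyric acid,2300.00,Sweaty,17.60,9.91,14.56,10.63
1-Propanol,54000.00,Alcoholic,17.53,14.53,13.35,16.60
Ethyl laurate,500.00,"Fruity, floral",15.16,17.58,9.13,13.77
Ethyl phenylacetate,407.00,"Rosy, floral, honey",11.94,8.01,9.09,8.12
Acetic acid,160000.00,"Vinegar, acidic",10.10,2.10,9.82,2.03
Hexyl hexanoate,1890.00,Fruity,8.79,5.61,7.63,4.93
Ethyl lactate,128000.00,Fruity,8.34,3.56,6.81,4.21
Valeric acid,389.00,Sweaty,7.15,9.72,5.49,3.24
Furfural,44000.00,"Nutty, sweet, bread",6.10,3.56,4.28,3.68
"(2R,3R)-(-)-2,3-Butanediol",12000.00,"Celery, fruity",4.26,2.10,4.32,2.21
Ethyl propanoate,19019.00,"Banana, fruity",3.50,1.86,3.61,2.46
Isobutanol,40000.00,Fruity,3.15,1.84,2.01,2.06
Ethyl hexanoate,13200.00,"Fruity, floral, sweet",2.72,2.33,2.51,2.09
Furfuryl alcohol,12323.00,"Caramel, sweet",2.51,1.59,2.43,2.32
Hexanol,5370.00,Floral,2.48,2.21,1.60,2.38
Ethyl myristate,500.00,"Sweet, waxy, violet orris",2.44,3.46,2.14,2.56
Propyl acetate,2700.00,"Fruity, sweet",1.61,1.19,1.05,1.07
3-Methylbutanol,179000.00,"Rancid, fusty, malt, green",1.51,0.87,0.92,0.87
"1,1-Diethoxy-3-methylbutane",323.00,"Fruity, fatty",1.44,2.72,0.86,2.87
Ethyl hexadecenoate,1500.00,"Fruity, creamy",1.16,0.28,1.00,0.31
2-Butanol,50000.00,"Fruity, alcoholic",1.06,0.88,0.77,0.67
Nonanoic acid,3559.00,Cheese,1.00,1.69,1.40,1.78
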