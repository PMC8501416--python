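trial,location_cm,location_oclock,initial_label,acquisition,diagnosis,n_cubes
3,37,8,suspicious,EMR x1,NDBE,12
3,37,4,control,Biopsy x1,NDBE,11
4,36,6,control,Biopsy x1,NDBE,60
5,31,9,control,Biopsy x1,NDBE,28
6,31,9,control,Biopsy x1,NDBE,6
6,28,6,control,Biopsy x1,NDBE,9
7,35,9,control,Biopsy x2,NDBE,8
7,32,5,control,Biopsy x2,NDBE,7
8,32,12,control,Biopsy x1,NDBE,32
8,30,6,control,Biopsy x1,NDBE,4
9,34,3,suspicious,EMR x1,IMC,9
9,33,3,suspicious,EMR x1,IMC,15
9,30,9,control,Biopsy x1,NDBE,5
10,32,10,suspicious,Biopsy x2,HGD,8
10,24,10,control,Biopsy x1,NDBE,7
11,35,12,suspicious,EMR x1,HGD,8
11,36,6,control,Biopsy x1,NDBE,15
12,41,6,suspicious,EMR x1,LGD,30
12,39,8,control,none,NA,5
12,39,6,control,Biopsy x1,LGD,3
14,36,3,suspicious,Biopsy x2,NDBE,8
14,38,3,control,Biopsy x1,NDBE,7
15,35-38,9,suspicious,EMR x4,IMC,11
15,37,3,control,Biopsy x1,NDBE,8
16,40,11,suspicious,Biopsy x1,IMC,7
16,39,3,control,Biopsy x1,NDBE,4
17,37,1,suspicious,Biopsy x2,NDBE,7
18,26,12,suspicious,EMR x2,HGD,134
18,25,9,control,Biopsy x1,NDBE,95
18,26,3,suspicious,EMR x1,HGD,7
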