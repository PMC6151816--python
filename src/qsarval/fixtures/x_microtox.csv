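id,name,observed,calculated,set
1,"1,1-dichloroethene",3.1549,3.3214,train
2,dichloromethane,2.2840,3.1963,train
3,bromochloromethane,5.0706,4.4813,train
4,chloroform,2.4318,2.4675,train
5,bromodichloromethane,5.0269,4.7723,train
6,bromoform,3.6383,3.2549,test
7,dibromochloromethane,3.0000,3.0193,test
8,dichloroiodomethane,3.4949,3.5960,test
9,bromochloroiodomethane,1.6021,2.2717,train
10,dibromoiodomethane,4.0506,4.0353,test
11,chlorodiiodomethane,4.6576,4.4046,train
12,bromodiiodomethane,5.6021,3.8512,train
13,triiodomethane,2.4202,2.6149,train
14,trichloronitromethane,4.3098,3.7132,train
15,tribromonitromethane,2.7447,2.7705,train
16,dichloroacetonitrile,4.5086,3.7184,train
17,trichloroacetonitrile,4.8861,4.2672,train
18,bromochloroacetonitrile,4.0132,3.8159,train
19,dibromoacetonitrile,4.7696,3.9655,train
20,"1,1-dichloropropanone",2.7212,4.0555,train
21,"1,1,1-trichloropropanone",3.6576,3.4857,test
22,chloroacetic acid,6.0088,5.6592,train
23,bromoacetic acid,1.8861,3.2782,train
24,iodoacetic acid,2.6778,3.8068,train
25,dichloroacetic acid,3.2147,4.0622,train
26,bromochloroacetic acid,5.1612,4.4508,train
27,dibromoacetic acid,4.1487,4.1865,train
28,chloroiodoacetic acid,1.8239,2.9267,train
29,bromoiodoacetic acid,3.7959,3.8762,test
30,trichloroacetic acid,3.2924,3.6489,train
31,bromodichloroacetic acid,1.4318,2.4029,train
32,dibromochloroacetic acid,3.5229,2.6718,train
33,tribromoacetic acid,4.4202,3.2073,train
34,chloral hydrate,2.1675,2.2067,train
35,dichloracetamide,6.5229,6.9769,train
36,bromochloroacetamide,2.5686,2.9516,test
37,dibromoacetamide,3.0706,3.2043,train
38,chloroiodoacetamide,2.6576,3.3142,train
39,bromoiodoacetamide,3.3768,4.4729,train
40,diiodoacetamide,1.4318,1.1768,train
41,trichloroacetamide,2.0000,1.8559,train
42,bromodichloroacetamide,4.3098,4.099,test
43,dibromochloroacetamide,4.3768,4.2953,test
44,tribromoacetamide,2.1308,1.5148,train
45,n-nitrosodimethylamine,2.9208,3.0246,train
46,n-nitrosodiethylamine,7.4202,7.1686,train
47,n-nitrosopiperidine,3.8861,4.6292,train
48,n-nitrosomorpholine,3.8539,3.3096,train
49,nitrosodi-n-butylamine,3.5850,3.4285,test
50,3-chloro-4-(dichloromethyl)-5-hydroxy-2(5H)-furanone,4.7447,3.1323,train
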