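id,name,observed,calculated,set
1,"1,1-dichloroethene",1.4145,2.4357,train
2,dichloromethane,0.8861,0.7818,train
3,bromochloromethane,0.7328,1.8741,train
4,chloroform,1.4089,1.0149,test
5,bromodichloromethane,1.4034,1.9032,train
6,bromoform,1.5850,1.9863,train
7,dibromochloromethane,1.9208,2.0116,train
8,dichloroiodomethane,3.2076,3.4508,train
9,bromochloroiodomethane,3.3279,3.3766,test
10,dibromoiodomethane,3.4559,3.2854,train
11,chlorodiiodomethane,3.6990,3.3999,train
12,bromodiiodomethane,3.5850,3.3046,train
13,triiodomethane,3.9337,3.3188,train
14,trichloronitromethane,5.3143,4.9812,train
15,tribromonitromethane,6.4949,6.0793,train
16,dichloroacetonitrile,3.7632,2.5119,test
17,trichloroacetonitrile,3.7447,2.6486,train
18,bromochloroacetonitrile,4.2757,4.2982,train
19,dibromoacetonitrile,4.7825,5.0416,test
20,"1,1-dichloropropanone",3.3188,2.2263,train
21,"1,1,1-trichloropropanone",2.7364,2.3615,train
22,chloroacetic acid,1.9851,1.6179,train
23,bromoacetic acid,4.2111,2.8428,train
24,iodoacetic acid,4.7212,4.305,test
25,dichloroacetic acid,1.5229,1.7669,train
26,bromochloroacetic acid,2.3565,2.8669,train
27,dibromoacetic acid,2.4318,2.9289,test
28,chloroiodoacetic acid,4.5302,4.3246,train
29,bromoiodoacetic acid,4.0200,4.3157,train
30,trichloroacetic acid,1.4034,2.0112,train
31,bromodichloroacetic acid,2.9031,2.8964,test
32,dibromochloroacetic acid,2.8539,2.9584,train
33,tribromoacetic acid,3.6882,3.0113,train
34,chloral hydrate,2.1707,2.1359,train
35,dichloracetamide,1.2798,1.5222,train
36,bromochloroacetamide,2.3565,3.3043,train
37,dibromoacetamide,4.2596,4.0477,train
38,chloroiodoacetamide,4.1192,4.0810,train
39,bromoiodoacetamide,3.7959,4.7536,test
40,diiodoacetamide,3.0482,4.1155,train
41,trichloroacetamide,0.7825,1.6577,test
42,bromodichloroacetamide,3.8239,3.3331,train
43,dibromochloroacetamide,4.3188,4.0764,train
44,tribromoacetamide,4.6676,4.8106,train
50,3-chloro-4-(dichloromethyl)-5-hydroxy-2(5H)-furanone,5.6108,6.4454,train
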