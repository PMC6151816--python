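id,name,observed,calculated,set
1,"1,1-dichloroethene",1.0706,1.7985,test
2,dichloromethane,0.8539,1.6828,train
3,bromochloromethane,0.6021,1.7808,train
4,chloroform,1.1675,1.2621,test
5,bromodichloromethane,1.3188,1.6196,train
6,bromoform,1.0862,1.9166,train
7,dibromochloromethane,1.6990,1.8321,test
8,dichloroiodomethane,2.1938,1.8353,train
9,bromochloroiodomethane,2.2291,2.9723,train
10,dibromoiodomethane,2.0000,1.9755,test
11,chlorodiiodomethane,2.4437,2.0457,test
12,bromodiiodomethane,3.0506,1.9836,train
13,triiodomethane,2.8861,1.9398,train
14,trichloronitromethane,4.2007,4.2819,test
15,tribromonitromethane,4.8861,5.0640,train
16,dichloroacetonitrile,3.0362,2.5123,train
17,trichloroacetonitrile,3.7447,3.8560,train
18,bromochloroacetonitrile,3.8539,3.3736,train
19,dibromoacetonitrile,4.2291,4.1282,train
20,"1,1-dichloropropanone",2.4318,2.2303,test
21,"1,1,1-trichloropropanone",2.3872,1.0225,train
22,chloroacetic acid,1.6990,1.0652,train
23,bromoacetic acid,4.0655,3.3127,train
24,iodoacetic acid,3.7447,2.4730,train
25,dichloroacetic acid,0.9208,1.2745,train
26,bromochloroacetic acid,1.1938,1.9983,test
27,dibromoacetic acid,1.6021,2.1776,train
28,chloroiodoacetic acid,4.0362,4.7239,train
29,bromoiodoacetic acid,3.7212,4.8968,test
30,trichloroacetic acid,1.0555,1.5905,train
31,bromodichloroacetic acid,1.7959,2.0658,train
32,dibromochloroacetic acid,1.4815,2.1417,train
33,tribromoacetic acid,2.1805,2.3490,train
34,chloral hydrate,1.3098,1.7185,train
35,dichloracetamide,0.5850,1.5056,train
36,bromochloroacetamide,1.4559,2.8215,train
37,dibromoacetamide,3.9586,3.6467,train
38,chloroiodoacetamide,2.7212,2.0333,train
39,bromoiodoacetamide,2.2291,1.9651,train
40,diiodoacetamide,2.2218,2.1941,train
41,trichloroacetamide,1.0706,1.4651,train
42,bromodichloroacetamide,4.0315,2.6693,train
43,dibromochloroacetamide,3.9586,3.8000,train
44,tribromoacetamide,4.4437,4.7359,train
50,3-chloro-4-(dichloromethyl)-5-hydroxy-2(5H)-furanone,4.8861,4.3949,train
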