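id,name,observed,calculated,set
1,"1,1-dichloroethene",0.4318,1.6512,train
2,dichloromethane,0.7212,0.9997,train
4,chloroform,1.0809,0.6385,train
5,bromodichloromethane,1.5686,1.2324,test
6,bromoform,1.1675,1.9629,train
7,dibromochloromethane,1.5528,1.6647,test
8,dichloroiodomethane,2.3279,1.6163,train
9,bromochloroiodomethane,2.3188,1.9777,train
10,dibromoiodomethane,1.9586,2.2126,train
11,chlorodiiodomethane,2.3098,2.2495,train
12,bromodiiodomethane,2.9586,2.4210,test
13,triiodomethane,2.8861,2.5894,train
14,trichloronitromethane,4.0809,3.3428,train
15,tribromonitromethane,4.7447,4.7139,train
16,dichloroacetonitrile,2.8239,2.9808,train
17,trichloroacetonitrile,3.4815,3.0753,train
18,bromochloroacetonitrile,3.7212,3.3159,train
19,dibromoacetonitrile,4.1938,3.5113,train
20,"1,1-dichloropropanone",2.3565,2.7129,train
21,"1,1,1-trichloropropanone",3.0000,2.2423,train
22,chloroacetic acid,1.6576,2.3448,train
23,bromoacetic acid,4.0000,3.1346,train
24,iodoacetic acid,3.6576,3.8483,train
25,dichloroacetic acid,0.6198,1.1912,train
26,bromochloroacetic acid,1.6990,1.8777,test
27,dibromoacetic acid,1.8861,2.2108,test
28,chloroiodoacetic acid,4.1024,4.8634,test
29,bromoiodoacetic acid,3.8861,5.1786,train
30,trichloroacetic acid,1.0506,1.6881,train
31,bromodichloroacetic acid,1.6576,0.6340,train
32,dibromochloroacetic acid,1.4559,2.7074,train
33,tribromoacetic acid,2.6021,2.9859,test
34,chloral hydrate,1.6778,1.9750,train
35,dichloracetamide,1.0506,1.6881,train
36,bromochloroacetamide,1.8239,2.4295,test
37,dibromoacetamide,3.6198,2.7807,train
38,chloroiodoacetamide,2.5376,2.1670,train
39,bromoiodoacetamide,2.0706,2.4718,train
40,diiodoacetamide,2.1938,2.1785,train
41,trichloroacetamide,1.5850,2.1329,train
42,bromodichloroacetamide,3.7959,2.7569,train
43,dibromochloroacetamide,3.6383,3.1107,train
44,tribromoacetamide,4.2147,3.4421,test
50,3-chloro-4-(dichloromethyl)-5-hydroxy-2(5H)-furanone,4.9586,4.7578,train
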