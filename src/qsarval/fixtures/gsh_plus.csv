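id,name,observed,calculated,set
1,"1,1-dichloroethene",1.3516,2.4847,train
2,dichloromethane,1.0888,0.7391,test
3,bromochloromethane,1.2182,1.6474,train
4,chloroform,1.2366,0.9330,train
5,bromodichloromethane,1.2111,1.7614,test
6,bromoform,1.0066,1.7407,train
7,dibromochloromethane,2.0809,1.7617,train
8,dichloroiodomethane,2.7959,2.9585,train
9,bromochloroiodomethane,2.7959,2.8967,train
10,dibromoiodomethane,2.8697,2.8209,test
11,chlorodiiodomethane,3.0809,2.9161,train
12,bromodiiodomethane,3.0969,2.8369,test
13,triiodomethane,3.3615,2.8486,train
14,trichloronitromethane,4.6383,4.2152,train
15,tribromonitromethane,5.3820,5.1283,train
16,dichloroacetonitrile,3.2757,2.5481,train
17,trichloroacetonitrile,3.8979,2.6617,train
18,bromochloroacetonitrile,4.3188,4.1067,train
19,dibromoacetonitrile,4.7100,4.7981,train
20,"1,1-dichloropropanone",3.0506,2.2187,test
21,"1,1,1-trichloropropanone",2.2803,2.3311,train
22,chloroacetic acid,2.1367,1.5737,train
23,bromoacetic acid,3.8697,2.5921,train
24,iodoacetic acid,4.3768,3.8079,test
25,dichloroacetic acid,1.2967,1.6975,train
26,bromochloroacetic acid,2.0783,2.6122,train
27,dibromoacetic acid,2.2403,2.6637,train
28,chloroiodoacetic acid,4.4034,3.8242,train
29,bromoiodoacetic acid,4.2403,3.8168,test
30,trichloroacetic acid,1.4034,1.8108,train
31,bromodichloroacetic acid,2.7100,2.6367,train
32,dibromochloroacetic acid,2.7959,2.6882,train
33,tribromoacetic acid,3.3372,2.7322,train
34,chloral hydrate,2.2636,2.1046,train
35,dichloracetamide,1.1135,1.4161,train
36,bromochloroacetamide,1.8539,2.9712,test
37,dibromoacetamide,4.2218,3.6626,test
38,chloroiodoacetamide,3.7212,3.5437,train
39,bromoiodoacetamide,3.1163,4.1762,train
40,diiodoacetamide,2.7825,3.5724,train
41,trichloroacetamide,0.3565,1.5288,train
42,bromodichloroacetamide,3.6198,2.9951,train
43,dibromochloroacetamide,3.9566,3.6865,train
44,tribromoacetamide,4.3233,4.3703,train
50,3-chloro-4-(dichloromethyl)-5-hydroxy-2(5H)-furanone,5.2596,6.0139,train
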