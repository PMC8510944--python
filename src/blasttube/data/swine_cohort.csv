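id,body_weight_kg,body_armor,organ_damage,respiratory_arrest,outcome
1,36.5,No,"LH, Hemothorax, Splenic injury, IAH",Yes,Death
2,34.5,No,"LH, Splenic injury, IAH",Yes,Death
3,39,No,"LH, Splenic injury, IAH",Yes,Death
4,39,No,"LH, Hemothorax, Splenic injury, IAH",Yes,Death
5,40,No,"LH, Hemothorax, Splenic injury, BR, IAH",Yes,Death
6,40,No,"LH, Splenic injury, IAH",No,Survival
7,39,No,"LH, Hemothorax",No,Survival
8,37.5,No,"LH, Hemothorax, Splenic injury, IAH",No,Survival
9,37,No,"LH, Splenic injury, IAH",Yes,Survival
10,48,No,"LH, Splenic injury, IAH",No,Survival
11,36,No,"LH, Splenic injury, IAH",No,Survival
12,36,Yes,"LH",No,Survival
13,38,Yes,"LH, Splenic injury, IAH",No,Survival
14,36,Yes,"LH, Splenic injury, IAH",No,Survival
15,39,Yes,"LH, Splenic injury, IAH",Yes,Survival
16,35.5,Yes,"LH",No,Survival
17,39.5,Yes,"LH, Splenic & Liver injury, BR, IAH",Yes,Survival
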