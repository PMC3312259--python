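# source_set: synthetic-hydropathy-n2000-seed20260923
# radius: 5.0
# pseudocount: 1.0
aa	n_in	n_out	e_star
A	1358	642	-0.7483596899
C	1507	493	-1.116004031
D	349	1651	1.5518088
E	379	1621	1.451243982
F	1546	454	-1.223775432
G	921	1079	0.1581710966
H	399	1601	1.387543581
I	1760	240	-1.988840175
K	292	1708	1.763491074
L	1692	308	-1.700916105
M	1377	623	-0.7922380832
N	346	1654	1.562231508
P	662	1338	0.7029033555
Q	367	1633	1.490703337
R	262	1738	1.888911482
S	831	1169	0.340926587
T	888	1112	0.2247171158
V	1740	260	-1.897694532
W	793	1207	0.4196379172
Y	734	1266	0.5445366811
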