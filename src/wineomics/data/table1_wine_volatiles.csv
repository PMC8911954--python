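num,rt_min,ri,name,id_level,ab_lachanga_2017,ab_lachanga_2018,ab_losdolores_2017,ab_losdolores_2018,cas,formula
1,6.7,900,Ethyl acetate,2,9.2e8,7.6e8,1.2e9,5.4e8,141-78-6,C4H8O2
2,7.2,918,Methyl alcohol,2,1.7e7,1.5e7,1.4e7,1.7e7,67-56-1,CH4O
3,10.6,1028,Isobutyl acetate,2,6.4e6,6.4e6,8.2e6,6.4e6,110-19-0,C6H12O2
4,11.5,1051,Ethyl butyrate,2,6.5e7,5.6e7,4.6e7,6.9e7,105-54-4,C6H12O2
5,12.0,1064,1-Propanol,2,2.3e7,1.4e7,2.7e7,2.7e7,71-23-8,C3H8O
6,12.2,1068,Ethyl 2-methylbutyrate,2,1.3e7,2.9e6,1.2e7,ND,7452-79-1,C7H14O2
7,12.8,1084,Ethyl 3-methylbutyrate,2,2.5e7,5.3e6,2.2e7,5.7e6,108-64-5,C7H14O2
8,13.2,1093,Unknown 13.2265,2,ND,ND,1.7e6,ND,-,C9H20O2
9,14.6,1127,Isobutyl alcohol,2,1.1e8,1.2e8,9.5e6,1.1e8,78-83-1,C4H10O
10,15.0,1135,Isoamyl acetate,2,2.4e8,2.3e8,2.8e6,2.7e8,123-92-2,C7H14O2
11,15.3,1143,p-Xylene,3,ND,ND,ND,7.5e5,106-42-3,C8H10
12,16.6,1170,Unknown 16.5912,4,ND,ND,ND,1.1e6,-,C10H16
13,17.3,1182,1-Butanol,2,ND,4.6e6,ND,ND,71-36-3,C4H10O
14,20.8,1261,Styrene,2,5.4e6,5.4e6,2.9e6,7.2e6,100-42-5,C8H8
15,21.2,1268,p-Cymene,1,3.4e6,7.6e6,ND,1.3e6,99-87-6,C10H14
16,21.4,1273,Isoamyl butyrate,2,7.1e6,3.6e6,4.6e6,5.5e6,106-27-4,C9H18O2
17,21.8,1284,Hexyl acetate,2,7.5e6,8.6e6,7.6e6,1.0e7,142-92-7,C8H16O2
18,22.7,1301,Furfuryl ethyl ether,2,ND,ND,1.6e6,ND,1000450-02-5,C7H10O2
19,22.8,1306,Ethyl 3-hexenoate,3,ND,ND,ND,2.7e6,2396-83-0,C8H14O2
20,23.3,1319,Acetoin,2,4.7e6,ND,ND,ND,513-86-0,C4H8O2
21,23.9,1328,Unknown 23.8754,2,ND,2.3e6,2.3e6,ND,-,C10H18O
22,24.5,1343,4-Methyl-1-pentanol,2,6.1e6,3.3e6,ND,3.3e6,626-89-1,C6H14O
23,24.6,1345,Ethyl heptanoate,2,9.6e6,6.5e6,8.5e6,6.7e6,106-30-9,C9H18O2
24,25.1,1356,1-Hexanol,2,1.5e7,6.5e6,1.4e7,ND,111-27-3,C7H14O2
25,25.3,1359,Ethyl 2-hexanoate,2,5.4e6,3.9e6,6.1e6,7.8e6,1552-67-6,C8H14O2
26,25.5,1366,Isobutyl hexanoate,2,ND,ND,ND,2.2e6,105-79-3,C10H20O2
27,25.8,1372,Ethyl lactate,2,ND,1.2e8,ND,1.0e8,97-64-3,C5H10O3
28,26.2,1381,Hexyl formate,2,1.7e8,9.3e7,2.3e8,1.1e8,629-33-4,C6H14O
29,26.6,1391,"2,6-Dimethyl-5-heptenal",2,1.8e6,1.2e6,ND,1.4e6,106-72-9,C9H16O
30,27.2,1402,Methyl octanoate,2,1.3e7,1.3e7,7.5e6,1.9e7,111-11-5,C9H18O2
31,27.5,1411,trans-3-Hexen-1-ol,2,1.4e6,9.0e5,2.1e6,9.5e5,928-97-2,C6H12O
32,27.9,1419,3-Octanol,2,1.3e6,1.1e6,1.5e6,1.0e6,589-98-0,C8H18O
33,28.5,1433,cis-2-Hexen-1-ol,2,1.3e6,ND,1.7e6,ND,928-94-9,C6H12O
34,29.3,1453,Unknown 29.3449,4,ND,ND,2.3e9,ND,-,C10H20O2
35,30.3,1476,Acetic acid,2,2.3e8,3.6e8,4.0e8,2.3e8,64-19-7,C2H4O2
36,30.6,1482,1-Heptanol,2,1.5e7,ND,1.3e7,7.4e6,111-70-6,C7H16O
37,30.6,1482,Unknown 30.6066,4,3.6e6,ND,ND,ND,-,C5H4O2
38,31.3,1499,trans-Linalool oxide (furanoid),3,ND,ND,2.2e6,ND,34995-77-2,C10H18O2
39,31.4,1503,Ethyl 7-octenoate,3,1.4e6,9.7e5,ND,1.1e6,35194-38-8,C10H18O2
40,31.9,1513,2-Ethyl-1-hexanol,2,4.0e6,2.1e6,4.9e6,2.7e6,104-76-7,C8H18O
41,32.5,1527,Geranyl ethyl ether 1,3,1.0e6,7.3e5,ND,1.0e6,1000285-27-5,C12H22O
42,32.8,1536,1-Octanol,2,8.1e6,2.9e6,1.1e7,3.2e6,111-87-5,C8H18O
43,33.2,1545,2-Nonanol,2,6.8e6,6.2e6,7.8e6,5.7e6,628-99-9,C9H20O
44,33.5,1552,Ethyl nonanoate,2,8.4e6,6.6e6,ND,ND,123-29-5,C11H22O2
45,34.2,1569,Ethyl 2-hydroxy-4-methylpentanoate,2,1.1e7,7.5e6,7.0e6,5.9e6,10348-47-7,C8H16O3
46,34.2,1570,beta-Linalool,2,4.8e6,5.1e6,5.4e6,5.0e6,78-70-6,C10H18O
47,34.4,1575,"2,3-Butanediol",2,8.1e7,9.7e7,1.2e8,1.1e8,513-85-9,C4H10O2
48,34.8,1583,Unknown 34.7591,4,2.8e7,1.9e7,2.4e7,1.9e7,-,C8H18O
49,34.9,1588,Unknown 34.9582,4,7.9e5,2.6e5,7.0e5,ND,-,-
50,35.3,1596,Unknown 35.2873,4,2.0e7,8.8e6,2.4e7,9.5e6,-,C8H16O3
51,35.9,1611,Unknown 35.8931,4,2.6e7,3.5e7,3.9e7,3.5e7,-,C6H12O2
52,36.5,1627,Propylene glycol,3,5.4e6,4.4e6,6.5e6,5.5e6,57-55-6,C3H8O2
53,37.0,1642,Unknown 37.0675,4,2.7e6,2.3e6,3.8e6,ND,-,C12H24O
54,37.7,1657,Ethyl decanoate,2,7.5e8,ND,3.8e8,1.6e9,110-38-3,C12H24O2
55,38.1,1668,4-Methylbenzaldehyde,3,ND,ND,1.2e6,ND,104-87-0,C8H8O
56,38.5,1678,Isoamyl octanoate,2,1.7e7,1.0e7,8.7e6,2.0e7,2035-99-6,C13H26O2
57,38.8,1686,1-Nonanol,2,1.8e7,1.0e7,2.3e7,9.8e6,143-08-8,C9H20O
58,39.0,1691,Unknown 38.9824,4,1.5e6,ND,1.9e6,ND,-,C15H32
59,39.2,1696,Unknown 39.1966,4,9.2e6,6.1e6,1.0e7,7.0e6,-,C5H10O2
60,39.4,1702,Diethyl succinate,2,1.3e9,2.9e8,ND,3.5e8,123-25-1,C8H14O4
61,39.7,1710,Ethyl 9-decenoate,3,2.0e7,1.8e7,2.1e7,3.2e7,67233-91-4,C12H22O2
62,40.3,1725,alpha-Terpineol,2,ND,1.7e6,5.9e6,1.6e6,98-55-5,C10H18O
63,40.8,1738,Unknown 40.7705,2,4.5e6,1.8e6,5.6e6,2.6e6,-,C12H16O2
64,41.0,1744,2-Undecanol,3,ND,ND,1.6e6,ND,1653-30-1,C11H24O
65,41.1,1746,3-(Methylthio)-1-propanol,3,4.5e6,2.7e6,5.0e6,3.4e6,505-10-2,C4H10OS
66,41.3,1754,Unknown 41.3476,4,1.4e6,ND,2.1e6,ND,-,C11H12O3
67,41.5,1758,Unknown 41.5185,4,1.7e6,5.0e5,8.8e5,9.0e5,-,C13H16
68,41.8,1767,Octyl ether,3,ND,7.5e5,ND,8.9e5,629-82-3,C16H34O
69,42.2,1776,"trans-4-(1,1-Dimethylethyl)-cyclohexanol",3,ND,1.2e6,ND,ND,21862-63-5,C10H20O
70,42.6,1787,Decyl alcohol,2,9.4e6,9.8e6,9.1e6,9.7e6,112-30-1,C10H22O
71,42.7,1790,Unknown 42.6886,2,3.8e7,3.3e7,1.9e7,1.8e7,-,C8H9NO2
72,42.9,1794,Methyl salicylate,2,ND,ND,1.3e6,ND,119-36-8,C8H8O3
73,43.3,1807,Ethyl phenylacetate,2,2.3e6,7.0e5,3.3e6,8.2e5,101-97-3,C10H12O2
74,43.7,1818,Unknown 43.7419,4,4.5e6,1.8e6,3.7e6,2.1e6,-,C8H14O4
75,44.1,1828,Unknown 44.0789,4,1.0e6,6.2e5,ND,7.5e5,-,C14H22
76,44.4,1839,Phenethyl acetate,2,1.5e7,1.3e7,2.7e7,1.5e7,103-45-7,C10H12O2
77,44.7,1846,beta-Damascenone,2,3.5e6,5.8e6,4.0e6,7.1e6,23726-93-4,C13H18O
78,45.3,1863,Ethyl dodecanoate,2,2.7e7,2.9e7,1.7e7,2.4e7,106-33-2,C14H28O2
79,45.6,1872,Hexanoic acid,2,5.6e7,3.3e7,5.9e7,5.7e7,142-62-1,C6H12O2
80,46.0,1883,Isoamyl decanoate,2,2.4e6,1.1e6,1.1e6,1.6e6,2306-91-4,C15H30O2
81,46.7,1902,Benzyl alcohol,2,1.3e7,7.3e6,2.2e7,6.4e6,100-51-6,C7H8O
82,47.0,1912,Unknown 47.0219,2,6.7e5,6.0e5,7.0e5,ND,-,C16H30O4
83,47.6,1929,Ethyl 3-methylbutyl succinate,3,4.7e7,1.8e7,4.4e7,2.8e7,28024-16-0,C11H20O4
84,48.0,1940,2-Phenylethanol,2,1.4e9,1.1e9,ND,1.3e9,60-12-8,C8H10O
85,48.9,1967,Unknown 48.8990,4,ND,ND,6.8e6,ND,-,C7H5ClF3N
86,49.7,1991,1-Dodecanol,2,2.3e6,2.4e6,2.4e6,3.2e6,112-53-8,C12H26O
87,50.9,2032,Diphenyl ether,2,ND,ND,ND,2.5e5,101-84-8,C12H10O
88,51.7,2062,4-Ethylguaiacol,3,ND,ND,1.8e6,ND,2785-89-9,C9H12O2
89,52.0,2072,Unknown 51.9854,2,7.6e5,1.4e6,8.6e5,1.5e6,-,C15H26O3
90,52.1,2078,Ethyl tetradecanoate,3,7.0e5,1.2e6,3.8e5,6.4e5,124-06-1,C16H32O2
91,52.3,2084,Unknown 52.3099,4,ND,ND,4.6e5,ND,-,C10H20O2
92,52.5,2093,Octanoic acid,2,1.2e8,9.3e7,1.3e8,1.8e8,124-07-2,C8H16O2
93,54.4,2194,Unknown 54.4273,4,2.3e6,1.7e6,ND,ND,-,C8H7NO2
94,54.5,5197,4-Ethylphenol,2,ND,ND,3.5e7,ND,123-07-9,C8H10O
95,55.8,2274,Ethyl hexadecanoate,2,2.3e6,1.1e6,1.7e6,1.3e6,628-97-7,C18H36O2
96,56.1,2288,Unknown 56.0757,4,ND,ND,ND,1.7e5,-,C16H18
97,56.3,2301,Decanoic acid,2,7.7e6,1.0e7,6.1e6,1.9e7,334-48-5,C10H20O2
98,56.5,2313,Unknown 56.5471,4,8.2e5,5.6e5,7.3e5,7.3e5,-,C13H14ClF2NO3
99,56.8,2324,"2,4-Di-tert-butylphenol",2,1.2e7,2.4e6,1.3e7,2.7e6,96-76-4,C14H22O
100,57.4,2354,Ethyl trans-2-butenoate,2,ND,ND,2.0e7,ND,56-81-5,C3H8O3
101,58.9,2426,Ethyl hydrogen succinate,3,8.6e6,ND,ND,ND,1070-34-4,C6H10O4
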