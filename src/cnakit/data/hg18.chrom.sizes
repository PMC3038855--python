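1	247249719
2	242951149
3	199501827
4	191273063
5	180857866
6	170899992
7	158821424
8	146274826
9	140273252
10	135374737
11	134452384
12	132349534
13	114142980
14	106368585
15	100338915
16	88827254
17	78774742
18	76117153
19	63811651
20	62435964
21	46944323
22	49691432
X	154913754
Y	57772954
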