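rank	taxon	age_mya
1	Cellular organisms	4100
2	Eukaryota	1850
3	Metazoa	665
4	Chordata	541
5	Craniata	535
6	Vertebrata	525
7	Euteleostomi	420
8	Mammalia	225
9	Eutheria	160
10	Euarchontoglires	65
11	Primates	55
12	Haplorrhini	50
13	Catarrhini	44
14	Hominidae	17
15	Homo	2.8
16	Homo sapiens	0.35
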