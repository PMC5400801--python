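allele	subspecies	n_individuals	accession	novel_coding
Gogo-A*01:01:01	G. g. gorilla / diehli	5	KY189923	0
Gogo-A*01:01:02	G. g. gorilla	3	KY189924	1
Gogo-A*04:01:01:01	G. g. gorilla	17	KY189925	0
Gogo-A*04:01:01:02	G. g. gorilla	1	KY189926	0
Gogo-A*04:01:01:03	G. g. gorilla	5	KY189927	0
Gogo-A*04:01:01:04	G. g. gorilla	1	KY189928	0
Gogo-A*04:01:01:05	G. g. gorilla	10	KY189929	0
Gogo-A*07:01:01:01	G. g. gorilla	2	KY189930	1
Gogo-A*07:01:01:02	G. g. gorilla	1	KY189931	1
Gogo-Oko*01:01	G. g. gorilla	9	KY189932	0
Gogo-Oko*01:02	G. g. gorilla	2	KY189933	1
Gobe-Oko*01:01	G. b. graueri	1	KY189933	1
Gogo-Oko*02:01	G. g. gorilla	2	KY189934	1
Gogo-Oko*02:02	G. g. gorilla / diehli	2	KY189935	1
Gogo-A*05:02:01:01N	G. g. gorilla	12	KY189936	1
Gogo-A*05:02:01:02N	G. g. gorilla / diehli	12	KY189937	1
Gogo-A*05:03:01:01N	G. g. gorilla	6	KY189938	1
Gogo-A*05:03:01:02N	G. g. gorilla	6	KY189939	1
Gogo-A*05:03:01:03N	G. g. gorilla	5	KY189940	1
Gogo-A*05:04N	G. g. gorilla	2	KY189941	1
Gogo-B*01:01:01:01	G. g. gorilla / diehli	13	KY189942	0
Gogo-B*01:01:01:02	G. g. gorilla	2	KY189943	0
Gogo-B*01:02	G. g. gorilla	1	KY189944	0
Gogo-B*01:03	G. g. gorilla	8	KY189945	0
Gogo-B*01:04:01:01	G. g. gorilla	2	KY189946	1
Gogo-B*01:04:01:02	G. g. gorilla	1	KY189947	1
Gogo-B*02:01	G. g. gorilla	5	KY189948	0
Gogo-B*03:01	G. g. gorilla	6	KY189949	0
Gogo-B*03:02	G. g. diehli	1	KY189950	1
Gogo-B*03:03	G. g. gorilla	2	KY189951	1
Gogo-B*04:01:01:01	G. g. gorilla	1	KY189952	0
Gogo-B*04:01:01:02	G. g. gorilla	9	KY189953	0
Gogo-B*05:01	G. g. gorilla	3	KY189954	0
Gogo-B*05:02	G. g. gorilla	5	KY189955	0
Gogo-B*06:01	G. g. gorilla	2	KY189956	0
Gogo-B*07:01	G. g. gorilla	4	KY189957	0
Gogo-B*07:02	G. g. gorilla	2	KY189958	1
Gogo-B*07:03	G. g. gorilla	1	KY189959	1
Gogo-B*07:04	G. g. gorilla	1	KY189960	1
Gogo-B*12:01	G. g. gorilla	1	KY189961	1
Gobe-B*13:01	G. b. graueri	1	KY189962	1
Gogo-C*01:01:01	G. g. gorilla	11	KY189963	0
Gogo-C*01:01:02	G. g. gorilla	11	KY189964	0
Gogo-C*01:01:03	G. g. diehli	1	KY189965	1
Gogo-C*01:03	G. g. gorilla	1	KY189966	0
Gogo-C*01:04	G. g. gorilla	1	KY189967	1
Gogo-C*02:02	G. g. gorilla / diehli	5	KY189968	0
Gobe-C*02:01	G. b. graueri	1	KY189968	0
Gogo-C*02:03	G. g. gorilla	11	KY189969	0
Gogo-C*02:04:01:01	G. g. gorilla	2	KY189970	0
Gogo-C*02:04:01:02	G. g. gorilla	1	KY189971	0
Gogo-C*02:05	G. g. gorilla	2	KY189972	1
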