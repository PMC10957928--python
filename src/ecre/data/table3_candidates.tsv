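region_id	location	distance_to_tss	gene	upregulated_at_d4	prediction_score
chr2-32661523-32662398	intron 2	14928	Eng	yes	0.7015349
chr5-75961876-75963126	intron 10	15332	Kdr	yes	0.6563047
chr2-26474950-26475427	intron 15	41236	Notch1	no	0.6256454
chr8-104110355-104111309	intron 1	8730	Cdh5	yes	0.5127832
chr11-106713708-106714257	intron 2	36371	Pecam1	yes	0.4803304
chr5-147657600-147658539	intron 10	67472	Flt1	yes	0.3063491
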