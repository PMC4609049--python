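subcategory	n_gc	n_kn	pct_gc	pct_kn	p_adj_reported	reported_significant
Amino acid metabolism	374	242	7	10	1e-04	true
Carbohydrate metabolism	441	249	9	11	1e-02	true
Cell communication	152	38	3	2	5e-03	true
Cell growth and death	302	69	6	3	5e-06	true
Cell motility	107	30	2	1	4e-02	true
Energy metabolism	393	246	8	11	4e-04	true
Environmental adaptation	161	36	3	2	7e-04	true
Folding sorting and degradation	571	274	11	12	4e-01	false
Lipid metabolism	229	124	4	5	1e-01	false
Membrane transport	75	20	1	1	6e-02	false
Metabolism of other amino acids	129	82	3	4	2e-02	true
Nucleotide metabolism	297	99	6	4	2e-02	true
Replication and repair	156	45	3	2	2e-02	true
Signal transduction	583	154	11	7	3e-07	true
Transport and catabolism	356	129	7	6	6e-02	false
Translation	559	315	11	14	6e-03	true
Transcription	264	155	5	7	2e-02	true
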