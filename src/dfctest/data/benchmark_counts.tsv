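# Eleven public two-class microarray benchmark datasets (GEO accessions).
# n_class_a / n_class_b: samples per class; n_confirmed: RT-PCR-confirmed
# DEGs used as ROC truth; n_ka: reference catalogue entry number.
dataset	n_class_a	n_class_b	n_confirmed	n_ka
GSE8441	11	11	9	5
GSE9499	15	7	77	6
GSE2639	7	7	13	8
GSE2638	3	4	16	9
GSE3860	9	9	8	11
GSE6344	10	10	19	15
GSE7765	3	3	13	18
GSE6740_1	10	10	40	24
GSE6740_2	10	10	62	25
GSE6011	14	23	10	30
GSE2531	3	4	17	36
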