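# Published AUC values of three rankers (welch t-test, shrinkage t-test,
# distributional fold change test) on the eleven benchmark datasets, under
# two preprocessing pipelines (mas5, rma). n_samples: total samples used.
dataset	n_samples	preprocessing	method	auc
GSE8441	22	mas5	t_test	0.92912
GSE8441	22	mas5	shrink_t	0.94404
GSE8441	22	mas5	dfc	0.96996
GSE9499	22	mas5	t_test	0.96425
GSE9499	22	mas5	shrink_t	0.98255
GSE9499	22	mas5	dfc	0.98529
GSE2639	14	mas5	t_test	0.99782
GSE2639	14	mas5	shrink_t	0.99838
GSE2639	14	mas5	dfc	0.9987
GSE2638	7	mas5	t_test	0.79197
GSE2638	7	mas5	shrink_t	0.83621
GSE2638	7	mas5	dfc	0.86199
GSE3860	18	mas5	t_test	0.98986
GSE3860	18	mas5	shrink_t	0.99581
GSE3860	18	mas5	dfc	0.99742
GSE6344	20	mas5	t_test	0.97165
GSE6344	20	mas5	shrink_t	0.98078
GSE6344	20	mas5	dfc	0.98854
GSE7765	6	mas5	t_test	0.96323
GSE7765	6	mas5	shrink_t	0.97846
GSE7765	6	mas5	dfc	0.98564
GSE6740_1	20	mas5	t_test	0.99491
GSE6740_1	20	mas5	shrink_t	0.99676
GSE6740_1	20	mas5	dfc	0.99701
GSE6740_2	20	mas5	t_test	0.99115
GSE6740_2	20	mas5	shrink_t	0.99313
GSE6740_2	20	mas5	dfc	0.99283
GSE6011	37	mas5	t_test	0.86072
GSE6011	37	mas5	shrink_t	0.8674
GSE6011	37	mas5	dfc	0.90942
GSE2531	7	mas5	t_test	0.91614
GSE2531	7	mas5	shrink_t	0.94288
GSE2531	7	mas5	dfc	0.9379
GSE8441	22	rma	t_test	0.91206
GSE8441	22	rma	shrink_t	0.92842
GSE8441	22	rma	dfc	0.96812
GSE9499	22	rma	t_test	0.94735
GSE9499	22	rma	shrink_t	0.97241
GSE9499	22	rma	dfc	0.9718
GSE2639	14	rma	t_test	0.99851
GSE2639	14	rma	shrink_t	0.99784
GSE2639	14	rma	dfc	0.99896
GSE2638	7	rma	t_test	0.75527
GSE2638	7	rma	shrink_t	0.82421
GSE2638	7	rma	dfc	0.83175
GSE3860	18	rma	t_test	0.98647
GSE3860	18	rma	shrink_t	0.99246
GSE3860	18	rma	dfc	0.99568
GSE6344	20	rma	t_test	0.97586
GSE6344	20	rma	shrink_t	0.98216
GSE6344	20	rma	dfc	0.9889
GSE7765	6	rma	t_test	0.96267
GSE7765	6	rma	shrink_t	0.98146
GSE7765	6	rma	dfc	0.98939
GSE6740_1	20	rma	t_test	0.9972
GSE6740_1	20	rma	shrink_t	0.99803
GSE6740_1	20	rma	dfc	0.99803
GSE6740_2	20	rma	t_test	0.97599
GSE6740_2	20	rma	shrink_t	0.98248
GSE6740_2	20	rma	dfc	0.98487
GSE6011	37	rma	t_test	0.97544
GSE6011	37	rma	shrink_t	0.98126
GSE6011	37	rma	dfc	0.97892
GSE2531	7	rma	t_test	0.93889
GSE2531	7	rma	shrink_t	0.94368
GSE2531	7	rma	dfc	0.94107
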